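"""Configuration objects for scenario and cohort simulation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class ScenarioConfig:
    """Structure of one 25-min, four-phase supervision scenario.

    The default phase plan is a 2-min waiting period with no stimuli (P1)
    followed by three attack phases of increasing difficulty (P2 7 min,
    P3 7 min, P4 9 min).  Difficulty is manipulated purely through the
    per-phase appearance rates of targets and messages, their dwell time
    on screen, and how concentrated target placement is across zones.

    Parameters
    ----------
    phase_durations : seconds per phase.
    target_rate_per_phase, message_rate_per_phase : appearances per
        minute for each phase; P1 must be 0 and rates must be
        non-decreasing from P2 to P4.
    mean_processing_time : mean seconds an item stays on screen.
    screen_grid : (rows, cols) of equal screen zones.
    spatial_concentration : per-phase geometric decay of zone weights;
        1 spreads targets uniformly over the zones, values near 0
        concentrate them in few zones (low spatial entropy).
    """

    phase_durations: tuple[float, ...] = (120.0, 420.0, 420.0, 540.0)
    target_rate_per_phase: tuple[float, ...] = (0.0, 3.0, 8.0, 14.0)
    message_rate_per_phase: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    mean_processing_time: float = 60.0
    screen_grid: tuple[int, int] = (2, 4)
    spatial_concentration: tuple[float, ...] = (0.3, 0.4, 0.7, 1.0)

    def __post_init__(self):
        for name in ("phase_durations", "target_rate_per_phase",
                     "message_rate_per_phase", "spatial_concentration"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must have exactly 4 phases")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        for rates in (self.target_rate_per_phase, self.message_rate_per_phase):
            if rates[0] != 0:
                raise ValueError("P1 is a waiting period: its rates must be 0")
            if any(a > b for a, b in zip(rates[1:], rates[2:])):
                raise ValueError("rates must be non-decreasing over P2..P4")
            if any(r < 0 for r in rates):
                raise ValueError("rates must be non-negative")
        if self.mean_processing_time <= 0:
            raise ValueError("mean_processing_time must be positive")
        if self.screen_grid[0] < 1 or self.screen_grid[1] < 1:
            raise ValueError("screen grid must have at least one zone")
        if any(not (0 < c <= 1) for c in self.spatial_concentration):
            raise ValueError("spatial_concentration must lie in (0, 1]")

    @property
    def total_duration(self) -> float:
        return float(sum(self.phase_durations))

    @property
    def phase_edges(self) -> tuple[float, ...]:
        edges = [0.0]
        for d in self.phase_durations:
            edges.append(edges[-1] + d)
        return tuple(edges)


@dataclass(frozen=True)
class ParticipantParams:
    """Physiological and subjective response parameters of one operator.

    Heart-rate variability decreases with load: the per-beat jitter sd is
    ``rr_baseline_sd − sdnn_load_slope × (TD−1)``, floored at 1 ms.  Pupil
    diameter dilates with load: mean ``pupil_baseline + pupil_load_gain ×
    (TD−1)`` mm on top of slow spontaneous drift (hippus) and sample noise.
    A fraction ``artifact_prob`` of pupil samples is replaced by
    out-of-range values in [0.5, 2) ∪ (8, 10] mm, the range the cleansing
    filter removes.  Subjective probes match the true difficulty with
    probability ``probe_fidelity``, else miss by one level.
    """

    rr_baseline_mean: float = 800.0   # ms
    rr_baseline_sd: float = 50.0      # ms
    sdnn_load_slope: float = 15.0     # ms per TD step
    pupil_baseline: float = 4.5       # mm
    pupil_load_gain: float = 0.35     # mm per TD step
    pupil_noise_sd: float = 0.3       # mm, per sample
    pupil_drift_sd: float = 0.12      # mm, slow AR(1) hippus component
    pupil_drift_tau: float = 10.0     # s, drift correlation time
    pupil_rate_hz: float = 60.0
    artifact_prob: float = 0.02
    probe_fidelity: float = 0.8
    likert_levels: int = 5

    def __post_init__(self):
        if self.rr_baseline_mean <= 0 or self.rr_baseline_sd <= 0:
            raise ValueError("RR baseline mean and sd must be positive")
        if self.pupil_noise_sd <= 0 or self.pupil_drift_sd < 0:
            raise ValueError("pupil noise sd must be positive")
        if not (2.0 < self.pupil_baseline < 8.0):
            raise ValueError("pupil_baseline must lie strictly within (2, 8) mm")
        for p in (self.artifact_prob, self.probe_fidelity):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pupil_rate_hz <= 0 or self.pupil_drift_tau <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.likert_levels < 3:
            raise ValueError("likert scale needs at least 3 levels")


@dataclass(frozen=True)
class CohortConfig:
    """A cohort: one scenario shared by ``n_participants`` operators.

    ``heterogeneity`` scales the between-participant spread of every
    physiological parameter around the population means given in
    ``population``; 0 makes all participants identical.
    """

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    n_participants: int = 17
    heterogeneity: float = 1.0
    baseline_duration: float = 300.0  # 5-min resting calibration
    population: ParticipantParams = field(default_factory=ParticipantParams)

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("cohort needs at least 2 participants")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        raw = json.loads(Path(path).read_text())
        scen = raw.pop("scenario", {})
        pop = raw.pop("population", {})
        scen = {k: tuple(v) if isinstance(v, list) else v for k, v in scen.items()}
        return cls(scenario=ScenarioConfig(**scen),
                   population=ParticipantParams(**pop), **raw)
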