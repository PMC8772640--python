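"""Seeded simulator for operator supervision sessions.

Generates everything the downstream analysis consumes, with the
statistical structure the analysis assumes baked in:

* an event log of target/message appearances over a four-phase scenario,
  with per-phase Poisson arrival rates, exponential on-screen lifetimes
  and a per-phase spatial concentration of targets across screen zones;
* RR-interval and pupil-diameter streams whose local variability
  (respectively mean dilation) track the true task difficulty;
* subjective probes (ISA 1–5 and a Likert difficulty rating) every 90 s,
  noisily agreeing with the true difficulty;
* a resting baseline recording used for z-normalization.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import CohortConfig, ParticipantParams, ScenarioConfig
from .difficulty import EVENT_COLUMNS, compute_td_series

__all__ = [
    "generate_event_log",
    "generate_physio",
    "generate_probes",
    "generate_baseline",
    "generate_cohort",
    "draw_participant_params",
    "SessionBundle",
    "write_session",
    "read_session",
]

# How many within-block ISA steps favour the lower level of a TD block:
# TD1 -> ISA 1/2, TD2 -> ISA 2/3, TD3 -> ISA 4/5.
_ISA_BLOCKS = {1: (1, 2), 2: (2, 3), 3: (4, 5)}
_ISA_LOWER_WEIGHT = 0.65


def _zone_probs(n_zones: int, concentration: float) -> np.ndarray:
    """Geometric zone weights: concentration 1 is uniform, ↓0 concentrates."""
    w = concentration ** np.arange(n_zones)
    return w / w.sum()


def generate_event_log(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Draw a scenario event log.

    Arrivals are Poisson within each phase at that phase's rate;
    each item stays on screen for an exponential time with mean
    ``config.mean_processing_time``; each target is placed in a zone
    drawn from the phase's concentration profile.  Messages occupy the
    message banner and carry zone (0, 0) by convention.

    Returns a DataFrame with columns :data:`~opstate.difficulty.EVENT_COLUMNS`,
    sorted by appearance time.
    """
    rng = np.random.default_rng(seed)
    rows, cols = config.screen_grid
    n_zones = rows * cols
    edges = config.phase_edges

    recs: list[tuple] = []
    for phase in range(4):
        t0, t1 = edges[phase], edges[phase + 1]
        for kind, rate in (("target", config.target_rate_per_phase[phase]),
                           ("message", config.message_rate_per_phase[phase])):
            if rate <= 0:
                continue
            n = rng.poisson(rate / 60.0 * (t1 - t0))
            t_appear = np.sort(rng.uniform(t0, t1, n))
            lifetime = rng.exponential(config.mean_processing_time, n)
            if kind == "target":
                p = _zone_probs(n_zones, config.spatial_concentration[phase])
                zones = rng.choice(n_zones, size=n, p=p)
            else:
                zones = np.zeros(n, dtype=int)
            for ta, lt, z in zip(t_appear, lifetime, zones):
                recs.append((ta, ta + lt, kind, z // cols, z % cols))
    log = pd.DataFrame(recs, columns=EVENT_COLUMNS)
    return log.sort_values("t_appear_s", kind="stable").reset_index(drop=True)


def _td_at(td_series: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    td = td_series["td"].to_numpy()
    t0 = float(td_series["t_s"].iloc[0])
    idx = np.clip((np.asarray(times, dtype=float) - t0).astype(int), 0, len(td) - 1)
    return td[idx]


def generate_physio(
    td_series: pd.DataFrame, params: ParticipantParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate RR intervals and pupil samples driven by the TD series.

    RR: consecutive beats with interval ``rr_baseline_mean`` plus Gaussian
    jitter whose sd is ``rr_baseline_sd − sdnn_load_slope·(TD−1)`` (floored
    at 1 ms), so windowed SDNN decreases with load.  Pupil: samples at
    ``pupil_rate_hz`` with mean ``pupil_baseline + pupil_load_gain·(TD−1)``,
    an AR(1) drift emulating hippus, white noise, and out-of-range
    artifacts injected with probability ``artifact_prob``.

    Returns ``(rr, pupil)`` DataFrames with columns ``(t_s, rr_ms)`` and
    ``(t_s, pd_mm)``.
    """
    if len(td_series) == 0:
        raise ValueError("td_series is empty")
    rng = np.random.default_rng(seed)
    span = float(len(td_series))

    td_arr = td_series["td"].to_numpy()
    t0 = float(td_series["t_s"].iloc[0])

    # --- RR stream (sequential; count is data-dependent) -------------
    beat_t, beat_rr = [], []
    t = 0.0
    while True:
        td = td_arr[min(max(int(t - t0), 0), len(td_arr) - 1)]
        sd = max(params.rr_baseline_sd - params.sdnn_load_slope * (td - 1), 1.0)
        rr = params.rr_baseline_mean + rng.normal(0.0, sd)
        rr = max(rr, 250.0)  # physiological floor
        t += rr / 1000.0
        if t > span:
            break
        beat_t.append(t)
        beat_rr.append(rr)
    rr_df = pd.DataFrame({"t_s": beat_t, "rr_ms": beat_rr})

    # --- pupil stream (vectorized) ------------------------------------
    dt = 1.0 / params.pupil_rate_hz
    n = int(round(span * params.pupil_rate_hz))
    t_pd = np.arange(n) * dt
    mean = params.pupil_baseline + params.pupil_load_gain * (_td_at(td_series, t_pd) - 1)
    a = np.exp(-dt / params.pupil_drift_tau)
    innov = rng.normal(0.0, params.pupil_drift_sd * np.sqrt(1 - a * a), n)
    drift = lfilter([1.0], [1.0, -a], innov)
    pdv = mean + drift + rng.normal(0.0, params.pupil_noise_sd, n)

    art = rng.random(n) < params.artifact_prob
    n_art = int(art.sum())
    if n_art:
        low = rng.random(n_art) < 0.5
        vals = np.where(low,
                        rng.uniform(0.5, 2.0, n_art),
                        rng.uniform(8.0, 10.0, n_art))
        # keep the artifact strictly outside the valid [2, 8] mm band
        vals = np.where(np.isclose(vals, 2.0), 1.99, vals)
        pdv[art] = vals
    pupil_df = pd.DataFrame({"t_s": t_pd, "pd_mm": pdv})
    return rr_df, pupil_df


def generate_probes(
    td_series: pd.DataFrame,
    params: ParticipantParams,
    seed: int,
    interval: float = 90.0,
) -> pd.DataFrame:
    """Simulate the on-screen subjective probes.

    Probes pop up every ``interval`` seconds.  The Likert difficulty
    answer equals the true TD with probability ``probe_fidelity`` and
    otherwise misses by one level; the ISA workload answer first applies
    the same fidelity noise on the TD scale, then maps each TD level into
    its ISA block (TD1→{1,2}, TD2→{2,3}, TD3→{4,5}) favouring the lower
    level of the block.

    Returns a DataFrame ``(t_s, true_td, isa, likert)``.
    """
    if len(td_series) == 0:
        raise ValueError("td_series is empty")
    rng = np.random.default_rng(seed)
    span = float(len(td_series))
    ticks = np.arange(interval, span + 1e-9, interval)
    true_td = _td_at(td_series, ticks)

    def noisy_td(td: np.ndarray) -> np.ndarray:
        miss = rng.random(td.size) >= params.probe_fidelity
        step = rng.choice([-1, 1], size=td.size)
        return np.clip(td + miss * step, 1, 3)

    likert = np.clip(noisy_td(true_td), 1, params.likert_levels)
    isa_td = noisy_td(true_td)
    lower = rng.random(isa_td.size) < _ISA_LOWER_WEIGHT
    blocks = np.array([_ISA_BLOCKS[v] for v in isa_td])
    isa = np.where(lower, blocks[:, 0], blocks[:, 1])
    return pd.DataFrame({
        "t_s": ticks,
        "true_td": true_td.astype(int),
        "isa": isa.astype(int),
        "likert": likert.astype(int),
    })


def generate_baseline(
    params: ParticipantParams, seed: int, duration: float = 300.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the resting calibration recording (lowest difficulty,
    no events): the source of z-normalization moments."""
    rest = pd.DataFrame({"t_s": np.arange(0.0, duration), "td": 1})
    return generate_physio(rest, params, seed)


@dataclass
class SessionBundle:
    """All recordings of one participant's session."""

    participant: str
    params: ParticipantParams
    events: pd.DataFrame
    td: pd.DataFrame
    rr: pd.DataFrame
    pupil: pd.DataFrame
    probes: pd.DataFrame
    baseline_rr: pd.DataFrame
    baseline_pupil: pd.DataFrame


# between-participant relative spreads at heterogeneity 1, and hard
# clipping ranges keeping drawn parameters physiologically sensible
_PARAM_SPREAD = {
    "rr_baseline_mean": (0.08, (600.0, 1100.0)),
    "rr_baseline_sd": (0.20, (20.0, 90.0)),
    "sdnn_load_slope": (0.30, (0.0, 35.0)),
    "pupil_baseline": (0.10, (3.2, 6.0)),
    "pupil_load_gain": (0.40, (0.05, 1.2)),
}


def draw_participant_params(
    population: ParticipantParams, heterogeneity: float, rng: np.random.Generator
) -> ParticipantParams:
    """Draw one participant's parameters around the population means."""
    updates = {}
    for name, (rel_sd, (lo, hi)) in _PARAM_SPREAD.items():
        mu = getattr(population, name)
        val = rng.normal(mu, heterogeneity * rel_sd * abs(mu)) if heterogeneity > 0 else mu
        updates[name] = float(np.clip(val, lo, hi))
    # keep the TD3 jitter sd comfortably positive
    updates["sdnn_load_slope"] = min(
        updates["sdnn_load_slope"], (updates["rr_baseline_sd"] - 5.0) / 2.0
    )
    return replace(population, **updates)


def generate_cohort(config: CohortConfig, seed: int) -> list[SessionBundle]:
    """Simulate a full cohort of participant sessions.

    Each participant gets individually drawn physiological parameters,
    their own scenario realization, physiological streams, probes and a
    resting baseline.  Deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    bundles = []
    for i in range(config.n_participants):
        params = draw_participant_params(config.population, config.heterogeneity, rng)
        s_events, s_phys, s_probe, s_base = rng.integers(0, 2**31 - 1, size=4)
        events = generate_event_log(config.scenario, int(s_events))
        td = compute_td_series(
            events, grid=config.scenario.screen_grid, span=config.scenario.total_duration
        )
        rr, pupil = generate_physio(td, params, int(s_phys))
        probes = generate_probes(td, params, int(s_probe))
        base_rr, base_pd = generate_baseline(params, int(s_base), config.baseline_duration)
        bundles.append(SessionBundle(
            participant=f"P{i + 1:02d}", params=params, events=events, td=td,
            rr=rr, pupil=pupil, probes=probes,
            baseline_rr=base_rr, baseline_pupil=base_pd,
        ))
    return bundles


_SESSION_FILES = {
    "events": "events.csv", "td": "td.csv", "rr": "rr.csv", "pupil": "pupil.csv",
    "probes": "probes.csv", "baseline_rr": "baseline_rr.csv",
    "baseline_pupil": "baseline_pupil.csv",
}


def write_session(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write one session bundle as CSV files under ``out_dir/participant``."""
    d = Path(out_dir) / bundle.participant
    d.mkdir(parents=True, exist_ok=True)
    for attr, fname in _SESSION_FILES.items():
        getattr(bundle, attr).to_csv(d / fname, index=False)
    return d


def read_session(session_dir: str | Path, participant: str | None = None) -> SessionBundle:
    """Read a session bundle previously written by :func:`write_session`."""
    d = Path(session_dir)
    frames = {attr: pd.read_csv(d / fname) for attr, fname in _SESSION_FILES.items()}
    return SessionBundle(participant=participant or d.name,
                         params=ParticipantParams(), **frames)
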