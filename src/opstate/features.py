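"""Per-second physiological features: windowed SDNN and cleaned pupil diameter.

Heart-rate variability is summarized by SDNN — the sample standard
deviation of the normal-to-normal (RR) intervals over the last 300
heartbeats.  Pupil samples outside the physiologically plausible
2–8 mm band are discarded as artifacts.  Both channels are averaged per
second and z-normalized against a resting baseline recording to remove
inter-individual level differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "sdnn",
    "hrv_series",
    "clean_pupil",
    "Baseline",
    "compute_baseline",
    "z_normalize",
    "build_feature_table",
]

PUPIL_MIN_MM = 2.0
PUPIL_MAX_MM = 8.0
SDNN_WINDOW_BEATS = 300
#: beats required before an SDNN value is emitted at scenario onset
SDNN_WARMUP_BEATS = 30


def sdnn(window: np.ndarray) -> float:
    """SDNN of one window of RR intervals (ms): sqrt(Σ(RRi − mRR)²/(N−1)).

    Raises ``ValueError`` for windows of fewer than two beats, where the
    sample standard deviation is undefined.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("SDNN needs at least 2 intervals")
    return float(np.std(window, ddof=1))


def hrv_series(
    rr: pd.DataFrame,
    window_beats: int = SDNN_WINDOW_BEATS,
    warmup_beats: int = SDNN_WARMUP_BEATS,
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-second SDNN over the most recent ``window_beats`` heartbeats.

    At each integer second t the window holds the last
    ``min(window_beats, available)`` beats with beat time ≤ t; before
    ``warmup_beats`` beats have accumulated the value is missing (NaN).

    Returns a DataFrame ``(t_s, hrv_ms, partial_window)`` where
    ``partial_window`` marks seconds computed from fewer than
    ``window_beats`` beats.
    """
    if len(rr) == 0:
        raise ValueError("empty RR series")
    t_beats = rr["t_s"].to_numpy(dtype=float)
    vals = rr["rr_ms"].to_numpy(dtype=float)
    if span is None:
        span = (0.0, float(np.ceil(t_beats[-1])))
    ticks = np.arange(np.floor(span[0]), span[1], 1.0)

    out = np.full(ticks.size, np.nan)
    partial = np.zeros(ticks.size, dtype=bool)
    hi = np.searchsorted(t_beats, ticks, side="right")
    for i, h in enumerate(hi):
        if h < warmup_beats:
            continue
        lo = max(0, h - window_beats)
        out[i] = np.std(vals[lo:h], ddof=1)
        partial[i] = h < window_beats
    return pd.DataFrame({"t_s": ticks, "hrv_ms": out, "partial_window": partial})


def clean_pupil(pupil: pd.DataFrame) -> pd.DataFrame:
    """Drop artifact samples: keep 2 mm ≤ pd ≤ 8 mm (bounds retained)."""
    pdv = pupil["pd_mm"].to_numpy(dtype=float)
    keep = (pdv >= PUPIL_MIN_MM) & (pdv <= PUPIL_MAX_MM)
    return pupil.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class Baseline:
    """Per-channel moments of the resting calibration recording."""

    hrv_mean: float
    hrv_sd: float
    pd_mean: float
    pd_sd: float

    def __post_init__(self):
        if self.hrv_sd <= 0 or self.pd_sd <= 0:
            raise ValueError("baseline sd must be positive")


def compute_baseline(baseline_rr: pd.DataFrame, baseline_pupil: pd.DataFrame) -> Baseline:
    """Derive z-normalization moments from the 5-min resting recording.

    Runs the same per-second pipeline (windowed SDNN, pupil cleansing and
    per-second averaging) on the rest data and takes the mean and sd of
    each resulting stream.
    """
    hrv = hrv_series(baseline_rr)["hrv_ms"].dropna()
    pd_sec = _per_second_pupil(clean_pupil(baseline_pupil))["pd_mm"].dropna()
    if len(hrv) < 2 or len(pd_sec) < 2:
        raise ValueError("baseline recording too short to estimate moments")
    return Baseline(
        hrv_mean=float(hrv.mean()), hrv_sd=float(hrv.std(ddof=1)),
        pd_mean=float(pd_sec.mean()), pd_sd=float(pd_sec.std(ddof=1)),
    )


def z_normalize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """(x − baseline mean) / baseline sd; errors on non-positive sd."""
    if sd <= 0:
        raise ValueError("baseline sd must be positive")
    return (np.asarray(values, dtype=float) - mean) / sd


def _per_second_pupil(pupil: pd.DataFrame) -> pd.DataFrame:
    sec = pupil["t_s"].to_numpy(dtype=float).astype(int)
    g = pd.DataFrame({"t_s": sec, "pd_mm": pupil["pd_mm"].to_numpy()})
    g = g.groupby("t_s", as_index=False)["pd_mm"].mean()
    return g.astype({"t_s": float})


def build_feature_table(
    rr: pd.DataFrame,
    pupil: pd.DataFrame,
    baseline: Baseline,
    span: tuple[float, float] | None = None,
    interpolate: bool = False,
) -> pd.DataFrame:
    """Join the per-second z-scored HRV and pupil channels.

    One row per second of the covered span, columns ``(t_s, hrv_z, pd_z)``.
    Seconds lacking either channel hold NaN and are expected to be dropped
    (not interpolated) before modelling; pass ``interpolate=True`` to
    fill interior gaps linearly instead.
    """
    if len(rr) == 0 or len(pupil) == 0:
        raise ValueError("empty physiological stream")
    if span is None:
        end = min(float(rr["t_s"].iloc[-1]), float(pupil["t_s"].iloc[-1]))
        span = (0.0, float(np.ceil(end)))
    if span[1] <= span[0]:
        raise ValueError("streams do not overlap")

    hrv = hrv_series(rr, span=span)
    pup = _per_second_pupil(clean_pupil(pupil))
    ticks = pd.DataFrame({"t_s": np.arange(span[0], span[1], 1.0)})
    tab = ticks.merge(hrv[["t_s", "hrv_ms"]], on="t_s", how="left")
    tab = tab.merge(pup, on="t_s", how="left")
    if interpolate:
        tab[["hrv_ms", "pd_mm"]] = tab[["hrv_ms", "pd_mm"]].interpolate(
            limit_area="inside"
        )
    tab["hrv_z"] = z_normalize(tab["hrv_ms"], baseline.hrv_mean, baseline.hrv_sd)
    tab["pd_z"] = z_normalize(tab["pd_mm"], baseline.pd_mean, baseline.pd_sd)
    return tab[["t_s", "hrv_z", "pd_z"]]
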