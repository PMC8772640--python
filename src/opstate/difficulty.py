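"""Dynamic task-difficulty (TD) labelling from a scenario event log.

The contextual difficulty of a supervision scenario is scored once per
second from three screen-state variables:

* ``N1`` — number of targets currently displayed and awaiting processing,
* ``N2`` — number of messages currently displayed and awaiting processing,
* ``Entropy`` — Shannon spatial entropy (nats) of the distribution of the
  displayed targets over a grid of equal screen zones (8 by default).

Each variable is discretized against fixed thresholds and the discrete
states are fused by a monotone rule table into a three-level difficulty
label ``TD ∈ {1, 2, 3}`` (low / medium / high), which downstream serves as
the supervision label for physiological-state classification.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "active_counts",
    "spatial_entropy",
    "discretize",
    "fuse_difficulty",
    "default_rule_table",
    "compute_td_series",
    "EVENT_COLUMNS",
]

#: Schema of an event log: one row per displayed item.
EVENT_COLUMNS = ["t_appear_s", "t_removed_s", "kind", "zone_row", "zone_col"]

# Discretization thresholds (inclusive on the left category, as printed
# in the scenario design: low ≤ 5 < medium ≤ 11 < high, etc.).
N1_LOW_MAX = 5
N1_MEDIUM_MAX = 11
N2_LOW_MAX = 2
ENTROPY_LOW_MAX = 0.45
ENTROPY_MEDIUM_MAX = 1.0


class Level(IntEnum):
    """Ordinal discretized state of a difficulty component."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


def _validate_log(log: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(log.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    if len(log) and (log["t_removed_s"] < log["t_appear_s"]).any():
        raise ValueError("event log has t_removed_s < t_appear_s")
    return log


def active_counts(log: pd.DataFrame, t: float, span: tuple[float, float] | None = None):
    """Count targets (N1) and messages (N2) active at time ``t``.

    An event is active on the half-open interval ``[t_appear, t_removed)``
    so a removal instant is never double-counted.

    Parameters
    ----------
    log : DataFrame with :data:`EVENT_COLUMNS`.
    t : query time in seconds.
    span : optional ``(start, end)``; a query outside it raises ``ValueError``.

    Returns
    -------
    (n1, n2) : integers.
    """
    _validate_log(log)
    if span is not None and not (span[0] <= t <= span[1]):
        raise ValueError(f"t={t} outside scenario span {span}")
    if len(log) == 0:
        return 0, 0
    alive = (log["t_appear_s"].to_numpy() <= t) & (t < log["t_removed_s"].to_numpy())
    kind = log["kind"].to_numpy()
    n1 = int(np.count_nonzero(alive & (kind == "target")))
    n2 = int(np.count_nonzero(alive & (kind == "message")))
    return n1, n2


def spatial_entropy(p: np.ndarray) -> float:
    """Shannon entropy H = −Σ p_i ln p_i (nats) of a zone distribution.

    ``0·ln 0`` is taken as 0.  An all-zero vector (no target displayed)
    yields 0 by convention: an empty screen is minimally demanding.

    Raises ``ValueError`` on negative proportions.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("zone proportions must be non-negative")
    total = p.sum()
    if total == 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def discretize(n1: int, n2: int, entropy: float) -> tuple[Level, Level, Level]:
    """Map raw (N1, N2, Entropy) to discrete states per the fixed thresholds.

    N1: low ≤ 5 < medium ≤ 11 < high.  N2: low ≤ 2 < high (binary).
    Entropy: low ≤ 0.45 < medium ≤ 1 < high.
    """
    if n1 <= N1_LOW_MAX:
        n1d = Level.LOW
    elif n1 <= N1_MEDIUM_MAX:
        n1d = Level.MEDIUM
    else:
        n1d = Level.HIGH
    n2d = Level.LOW if n2 <= N2_LOW_MAX else Level.HIGH
    if entropy <= ENTROPY_LOW_MAX:
        entropyd = Level.LOW
    elif entropy <= ENTROPY_MEDIUM_MAX:
        entropyd = Level.MEDIUM
    else:
        entropyd = Level.HIGH
    return n1d, n2d, entropyd


def fuse_difficulty(
    n1d: Level,
    n2d: Level,
    entropyd: Level,
    rule_table: dict[tuple[int, int, int], int] | None = None,
) -> int:
    """Fuse discretized components into TD ∈ {1, 2, 3}.

    Default rules (monotone completion of the single published High rule):

    * TD = 3 iff N1d = high and N2d = high and Entropyd ≥ medium
      (with a binary N2d, "≥ medium" can only mean high);
    * TD = 1 iff at most one component is above its minimum state;
    * TD = 2 otherwise.

    A full custom mapping ``{(n1d, n2d, entropyd): td}`` may be supplied.
    """
    if rule_table is not None:
        return rule_table[(int(n1d), int(n2d), int(entropyd))]
    if n1d == Level.HIGH and n2d == Level.HIGH and entropyd >= Level.MEDIUM:
        return 3
    above_min = sum(c > Level.LOW for c in (n1d, n2d, entropyd))
    return 1 if above_min <= 1 else 2


def default_rule_table() -> dict[tuple[int, int, int], int]:
    """The built-in fusion rules enumerated over all 18 component states."""
    table = {}
    for n1d in Level:
        for n2d in (Level.LOW, Level.HIGH):
            for ed in Level:
                table[(int(n1d), int(n2d), int(ed))] = fuse_difficulty(n1d, n2d, ed)
    return table


def compute_td_series(
    log: pd.DataFrame,
    grid: tuple[int, int] = (2, 4),
    span: float | tuple[float, float] = 1500.0,
    rule_table: dict[tuple[int, int, int], int] | None = None,
    rule: Callable[[Level, Level, Level], int] | None = None,
) -> pd.DataFrame:
    """Evaluate the TD label at 1 Hz over the scenario span.

    Parameters
    ----------
    log : event log DataFrame (:data:`EVENT_COLUMNS`).
    grid : screen zone grid (rows, cols); zones index the entropy bins.
    span : scenario length in seconds, or an explicit ``(start, end)``.
    rule_table, rule : optional overrides of the default fusion rules.

    Returns
    -------
    DataFrame with one row per second: ``t_s, n1, n2, entropy, n1d, n2d,
    entropyd, td``.  Discrete columns hold the names low/medium/high; ``td``
    holds 1, 2 or 3.
    """
    _validate_log(log)
    if np.isscalar(span):
        start, end = 0.0, float(span)
    else:
        start, end = map(float, span)
    if end <= start:
        raise ValueError("span must have positive length")
    ticks = np.arange(start, end, 1.0)

    n_zones = grid[0] * grid[1]
    appear = log["t_appear_s"].to_numpy(dtype=float)
    removed = log["t_removed_s"].to_numpy(dtype=float)
    kind = log["kind"].to_numpy()
    zone = (log["zone_row"].to_numpy() * grid[1] + log["zone_col"].to_numpy()).astype(int)
    if len(log) and (zone.min() < 0 or zone.max() >= n_zones):
        raise ValueError("event zone outside screen grid")

    is_target = kind == "target"
    rows = []
    for t in ticks:
        alive = (appear <= t) & (t < removed)
        tz = zone[alive & is_target]
        n1 = tz.size
        n2 = int(np.count_nonzero(alive & ~is_target))
        counts = np.bincount(tz, minlength=n_zones)
        h = spatial_entropy(counts)
        n1d, n2d, ed = discretize(n1, n2, h)
        if rule is not None:
            td = rule(n1d, n2d, ed)
        else:
            td = fuse_difficulty(n1d, n2d, ed, rule_table)
        rows.append((t, n1, n2, h, n1d.name.lower(), n2d.name.lower(), ed.name.lower(), td))
    return pd.DataFrame(
        rows, columns=["t_s", "n1", "n2", "entropy", "n1d", "n2d", "entropyd", "td"]
    )
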