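"""Validation statistics for the difficulty label and the OFS classes.

Two ordinal association checks validate the pipeline against subjective
experience:

* Spearman rank correlation between the task-difficulty label sampled at
  probe instants and the Likert difficulty ratings;
* an OFS × ISA contingency table (classifier classes against the 1–5
  Instantaneous Self-Assessment), with column percentages and the
  tie-corrected Kendall tau-b computed from the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_validation",
    "ContingencyTable",
    "build_contingency",
    "counts_from_percentages",
    "block_percentage",
    "kendall_tau_b",
    "build_report",
]

ISA_LEVELS = (1, 2, 3, 4, 5)
OFS_CLASSES = (1, 2, 3)


def spearman_validation(td_at_probes, ratings) -> tuple[float, float]:
    """Spearman rho (tie-corrected) and two-sided p for two ordinal series."""
    td_at_probes = np.asarray(td_at_probes)
    ratings = np.asarray(ratings)
    if td_at_probes.shape != ratings.shape:
        raise ValueError("series lengths differ")
    if td_at_probes.size < 3:
        raise ValueError("need at least 3 paired observations")
    res = stats.spearmanr(td_at_probes, ratings)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ContingencyTable:
    """ISA (rows 1–5) × OFS (columns 1–3) cross-tabulation.

    ``percentages`` are column percentages: each column sums to 100 up to
    rounding of its cells.  When the table is reconstructed from published
    percentages, the stored percentages are the given ones and ``counts``
    are derived; built from observations, percentages derive from counts.
    """

    counts: np.ndarray                      # shape (5, 3), ints
    percentages: np.ndarray = field(default=None)  # shape (5, 3)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(ISA_LEVELS), len(OFS_CLASSES)):
            raise ValueError("contingency table must be 5 ISA rows x 3 OFS columns")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.percentages is None:
            totals = self.counts.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                self.percentages = np.where(totals > 0,
                                            100.0 * self.counts / totals, 0.0)
        else:
            self.percentages = np.asarray(self.percentages, dtype=float)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"ISA{i}" for i in ISA_LEVELS],
                            columns=[f"OFS{j}" for j in OFS_CLASSES])


def build_contingency(ofs, isa) -> ContingencyTable:
    """Cross-tabulate paired OFS classes (1–3) and ISA levels (1–5)."""
    ofs = np.asarray(ofs, dtype=int)
    isa = np.asarray(isa, dtype=int)
    if ofs.shape != isa.shape:
        raise ValueError("series lengths differ")
    if not np.isin(ofs, OFS_CLASSES).all():
        raise ValueError("OFS codes must lie in 1..3")
    if not np.isin(isa, ISA_LEVELS).all():
        raise ValueError("ISA codes must lie in 1..5")
    counts = np.zeros((len(ISA_LEVELS), len(OFS_CLASSES)), dtype=int)
    for o, s in zip(ofs, isa):
        counts[s - 1, o - 1] += 1
    return ContingencyTable(counts=counts)


def counts_from_percentages(percentages, column_totals) -> ContingencyTable:
    """Reconstruct a table from published column percentages and totals.

    Each cell count is ``round(pct/100 × column total)``.  The given
    percentages are kept verbatim so block sums reproduce the published
    figures exactly.
    """
    percentages = np.asarray(percentages, dtype=float)
    column_totals = np.asarray(column_totals, dtype=float)
    counts = np.rint(percentages / 100.0 * column_totals).astype(int)
    return ContingencyTable(counts=counts, percentages=percentages)


def block_percentage(table: ContingencyTable, ofs_class: int, isa_levels) -> float:
    """Sum of column-percentage cells of one OFS class over a set of ISA levels."""
    if ofs_class not in OFS_CLASSES:
        raise ValueError("ofs_class must lie in 1..3")
    isa_levels = list(isa_levels)
    if any(l not in ISA_LEVELS for l in isa_levels):
        raise ValueError("isa levels must lie in 1..5")
    rows = [l - 1 for l in isa_levels]
    return float(table.percentages[rows, ofs_class - 1].sum())


def kendall_tau_b(table: ContingencyTable) -> float:
    """Tie-corrected Kendall tau-b from the cross-tabulation.

    tau-b = (C − D) / sqrt((n_pairs − T_row)(n_pairs − T_col)) with C/D the
    concordant/discordant pair counts and T the within-row/column tied
    pairs.  Undefined (raises) when all mass lies in one row or column.
    """
    c = table.counts.astype(float)
    if (c.sum(axis=1) > 0).sum() < 2 or (c.sum(axis=0) > 0).sum() < 2:
        raise ValueError("tau-b undefined: table degenerate in one row/column")
    n = c.sum()
    # concordant minus discordant via cumulative sums over the ordered grid
    C = D = 0.0
    R, K = c.shape
    for i in range(R):
        for j in range(K):
            if c[i, j] == 0:
                continue
            C += c[i, j] * c[i + 1:, j + 1:].sum()
            D += c[i, j] * c[i + 1:, :j].sum()
    n_pairs = n * (n - 1) / 2.0
    t_row = (c.sum(axis=1) * (c.sum(axis=1) - 1) / 2.0).sum()
    t_col = (c.sum(axis=0) * (c.sum(axis=0) - 1) / 2.0).sum()
    denom = np.sqrt((n_pairs - t_row) * (n_pairs - t_col))
    return float((C - D) / denom)


def build_report(
    td_validation: tuple[float, float] | None = None,
    pooled: dict | None = None,
    individual: dict | None = None,
    contingency: ContingencyTable | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble a serializable summary of every pipeline stage.

    Missing stages yield a partial report with a warning entry rather
    than an error, so intermediate runs remain inspectable.
    """
    report: dict = {"seed": seed, "config": config or {}, "warnings": []}
    if td_validation is not None:
        report["td_validation"] = {"spearman_rho": td_validation[0],
                                   "p_value": td_validation[1]}
    else:
        report["warnings"].append("td_validation missing")
    if pooled is not None:
        report["pooled"] = pooled
    else:
        report["warnings"].append("pooled layer missing")
    if individual is not None:
        report["individual"] = individual
    else:
        report["warnings"].append("individual layer missing")
    if contingency is not None:
        report["contingency"] = {
            "counts": contingency.counts.tolist(),
            "column_percentages": np.round(contingency.percentages).astype(int).tolist(),
            "column_totals": contingency.column_totals.tolist(),
            "kendall_tau_b": kendall_tau_b(contingency),
        }
    else:
        report["warnings"].append("contingency table missing")
    return report
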