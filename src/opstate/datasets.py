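"""Join physiological features to difficulty labels and build evaluation splits.

Two evaluation layers are supported:

* **pooled** — train on 13 of 17 participants, test on the 4 held out
  (no participant contributes rows to both sides);
* **individual** — per participant, a stratified 75/25 row split, with
  fourfold cross-validation on the training rows for hyperparameter
  tuning only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = ["align", "binarize", "make_splits", "SplitPlan", "BINARIZE_SCHEMES"]

#: pooled-layer proportions: 13 of 17 participants train, 4 test
POOLED_TRAIN_FRACTION = 13 / 17
INDIVIDUAL_TEST_FRACTION = 0.25
CV_FOLDS = 4

BINARIZE_SCHEMES = ("merge_low", "drop_medium")


def align(features: pd.DataFrame, td: pd.DataFrame, participant: str) -> pd.DataFrame:
    """Inner-join features and labels on the second; drop incomplete rows.

    Returns a labelled dataset ``(participant, t_s, hrv_z, pd_z, td)``.
    Raises ``ValueError`` when no second carries both channels and a label.
    """
    merged = features.merge(td[["t_s", "td"]], on="t_s", how="inner")
    merged = merged.dropna(subset=["hrv_z", "pd_z"]).reset_index(drop=True)
    if len(merged) == 0:
        raise ValueError("no overlapping labelled seconds with complete features")
    merged.insert(0, "participant", participant)
    return merged[["participant", "t_s", "hrv_z", "pd_z", "td"]]


def binarize(ds: pd.DataFrame, scheme: str = "merge_low") -> pd.DataFrame:
    """Collapse the 3-level difficulty label to {1 = low, 2 = high}.

    ``merge_low`` joins TD1 and TD2 into the low class and keeps TD3 as
    high — the operationally interesting contrast is detecting the
    high-risk state.  ``drop_medium`` discards TD2 rows instead.
    """
    if scheme not in BINARIZE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {BINARIZE_SCHEMES}")
    out = ds.copy()
    if scheme == "drop_medium":
        out = out[out["td"] != 2].reset_index(drop=True)
    out["td"] = np.where(out["td"] == 3, 2, 1)
    return out


@dataclass
class SplitPlan:
    """Serializable description of one train/test split."""

    layer: str                               # "pooled" | "individual"
    seed: int
    cv_folds: int = CV_FOLDS
    train_participants: list[str] = field(default_factory=list)
    test_participants: list[str] = field(default_factory=list)
    train_index: list[int] = field(default_factory=list)   # individual layer
    test_index: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        return cls(**json.loads(Path(path).read_text()))


def make_splits(
    data: pd.DataFrame | list[str],
    layer: str,
    seed: int,
    max_redraws: int = 20,
    temporal: bool = False,
) -> SplitPlan:
    """Build the split plan for one evaluation layer.

    Pooled layer: ``data`` is the participant list (or a labelled dataset,
    whose participants are used); 13/17 of them train, the rest test —
    proportions follow the 13-train/4-test protocol when the cohort size
    differs from 17.  Individual layer: ``data`` is one participant's
    labelled dataset; rows are split 75/25 stratified by label.

    Stratified draws that leave a class absent from either side are
    redrawn with a fresh derived seed (warning emitted by sklearn's
    stratifier is avoided by stratifying directly on the labels).

    ``temporal=True`` (individual layer only) replaces the stratified
    random draw with a contiguous block split — first 75% of seconds
    train, last 25% test.  Per-second rows are strongly autocorrelated
    (the HRV window alone spans minutes), so a random row split lets
    classifiers match test rows to temporal neighbours in the training
    set; the block split removes that leakage at the cost of a class mix
    that differs between the two sides.
    """
    rng = np.random.default_rng(seed)
    if layer == "pooled":
        participants = (sorted(pd.unique(data["participant"]))
                        if isinstance(data, pd.DataFrame) else sorted(data))
        n = len(participants)
        if n < 5:
            raise ValueError("pooled layer needs at least 5 participants")
        n_train = int(round(n * POOLED_TRAIN_FRACTION))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train = [participants[i] for i in perm[:n_train]]
        test = [participants[i] for i in perm[n_train:]]
        assert not set(train) & set(test), "participant leakage in pooled split"
        return SplitPlan(layer="pooled", seed=seed,
                         train_participants=sorted(train), test_participants=sorted(test))
    if layer != "individual":
        raise ValueError("layer must be 'pooled' or 'individual'")

    y = data["td"].to_numpy()
    idx = np.arange(len(y))
    if temporal:
        order = np.argsort(data["t_s"].to_numpy(), kind="stable")
        n_train = int(round(len(y) * (1 - INDIVIDUAL_TEST_FRACTION)))
        tr, te = order[:n_train], order[n_train:]
        if len(set(y[tr])) < 2:
            raise ValueError("temporal training block holds a single class")
        return SplitPlan(layer="individual", seed=seed,
                         train_index=sorted(int(i) for i in tr),
                         test_index=sorted(int(i) for i in te))
    for attempt in range(max_redraws):
        tr, te = train_test_split(
            idx, test_size=INDIVIDUAL_TEST_FRACTION, stratify=y,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        if set(y[tr]) == set(y) == set(y[te]):
            return SplitPlan(layer="individual", seed=seed,
                             train_index=sorted(int(i) for i in tr),
                             test_index=sorted(int(i) for i in te))
    raise ValueError("could not produce a stratified split with every class present")
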