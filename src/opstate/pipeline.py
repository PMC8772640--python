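"""End-to-end helpers wiring the stages together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import align
from .features import build_feature_table, compute_baseline
from .synthetic import SessionBundle

__all__ = ["process_session", "cohort_datasets", "predict_at_probes"]


def process_session(bundle: SessionBundle) -> pd.DataFrame:
    """Session bundle → labelled per-second dataset.

    Computes the baseline moments from the resting recording, builds the
    z-scored (hrv_z, pd_z) feature table for the scenario, and joins it
    to the per-second difficulty labels.
    """
    baseline = compute_baseline(bundle.baseline_rr, bundle.baseline_pupil)
    span = (0.0, float(len(bundle.td)))
    feats = build_feature_table(bundle.rr, bundle.pupil, baseline, span=span)
    return align(feats, bundle.td, bundle.participant)


def cohort_datasets(bundles: list[SessionBundle]) -> list[pd.DataFrame]:
    """Labelled dataset per participant, in cohort order."""
    return [process_session(b) for b in bundles]


def predict_at_probes(model, dataset: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Classifier OFS class at each probe instant, paired with ISA answers.

    For each probe, the feature row at the nearest labelled second (within
    2 s) feeds the classifier; probes without a nearby complete feature
    row are dropped.  Returns ``(t_s, ofs, isa, likert, td)``.
    """
    t_rows = dataset["t_s"].to_numpy()
    out = []
    for _, probe in probes.iterrows():
        i = int(np.argmin(np.abs(t_rows - probe["t_s"])))
        if abs(t_rows[i] - probe["t_s"]) > 2.0:
            continue
        row = dataset.iloc[[i]]
        ofs = int(model.predict(row[["hrv_z", "pd_z"]].to_numpy())[0])
        out.append((probe["t_s"], ofs, int(probe["isa"]), int(probe["likert"]),
                    int(row["td"].iloc[0])))
    return pd.DataFrame(out, columns=["t_s", "ofs", "isa", "likert", "td"])
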