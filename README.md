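# opstate

Classification of **operator functional state** (OFS) — an operator's
momentary risk of performance loss — from two psychophysiological
channels, heart-rate variability and pupil diameter, supervised by a
dynamic, contextual task-difficulty label.

The package targets researchers in human-factors / neuroergonomics who
want a fully synthetic, seeded test bench for this class of pipeline:
every stage of the analysis is implemented and testable without any
recorded human data.

## The method

A supervision scenario (one operator monitoring a drone swarm for
25 min across four phases P1–P4 of increasing demand) produces an event
log of targets and messages appearing on screen. From the log, each
second *t* receives a **task-difficulty label** TD(t) ∈ {1, 2, 3}:

1. raw context variables — N1(t), the number of displayed targets;
   N2(t), the number of displayed messages; and the spatial entropy
   H(t) = −Σᵢ pᵢ ln pᵢ of the target distribution over 8 equal screen
   zones;
2. discretization against fixed thresholds
   (N1: ≤5 / ≤11 / >11; N2: ≤2 / >2; H: ≤0.45 / ≤1 / >1);
3. monotone rule fusion — TD = 3 (high) iff N1 is high, N2 is high and
   entropy is at least medium; TD = 1 (low) iff at most one component is
   above its minimum; TD = 2 otherwise.

Physiological features are computed per second: **SDNN**, the sample
standard deviation √(Σ(RRᵢ − m)² / (N−1)) of the last 300 RR intervals,
and the mean **pupil diameter** after removing artifact samples outside
2–8 mm. Both are z-normalized against a 5-min resting baseline.

SVM (RBF / sigmoid / polynomial kernels, one-vs-one), kNN (Euclidean,
squared-Euclidean, Manhattan, Chebyshev) and random forests are tuned by
grid search with fourfold cross-validation and evaluated in 3-class and
binary (TD1+TD2 vs TD3) tasks at two layers: **pooled** (train on 13 of
17 participants, test on the held-out 4) and **individual** (75/25
stratified split per participant). The difficulty label is validated by
Spearman correlation against Likert probes collected every 90 s, and
the predicted OFS classes by an OFS × ISA contingency table with its
Kendall tau-b.

## Worked example

```python
import pandas as pd
from opstate import (CohortConfig, generate_cohort, cohort_datasets,
                     spearman_validation, train, predict_at_probes,
                     build_contingency, kendall_tau_b)
from opstate.classify import KnnSpec

cohort = generate_cohort(CohortConfig(n_participants=5), seed=42)
datasets = cohort_datasets(cohort)

rho, p = spearman_validation(
    pd.concat([b.probes["true_td"] for b in cohort]),
    pd.concat([b.probes["likert"] for b in cohort]))
print(f"TD vs Likert: Spearman rho = {rho:.3f} (p = {p:.2e})")

pairs = []
for b, ds in zip(cohort, datasets):
    model = train(ds.iloc[::2], KnnSpec(k=5))
    pairs.append(predict_at_probes(model, ds, b.probes))
pairs = pd.concat(pairs)
table = build_contingency(pairs["ofs"], pairs["isa"])
print(table.to_frame())
print(f"OFS vs ISA: Kendall tau-b = {kendall_tau_b(table):.2f}")
```

prints

```
TD vs Likert: Spearman rho = 0.875 (p = 2.40e-26)
      OFS1  OFS2  OFS3
ISA1    17     1     0
ISA2    12    27     0
ISA3     4     7     0
ISA4     0     1     6
ISA5     0     4     1
OFS vs ISA: Kendall tau-b = 0.58
```

The difficulty label correlates strongly with what the simulated
operators report (rho = 0.875 over 80 probes), and the per-probe OFS
predictions concentrate on the concordant diagonal of the contingency
table: low-risk seconds draw low ISA answers, high-risk seconds draw
ISA 4–5, with tau-b = 0.58 quantifying the ordinal association.

A command-line interface mirrors the stages:
`opstate simulate`, `opstate label`, `opstate features`,
`opstate train`, `opstate validate` (see `opstate --help`).

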