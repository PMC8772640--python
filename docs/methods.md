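# Methods

This note records the scientific and numerical choices behind the
package, what the synthetic data does and does not emulate, and the
known limitations of the evaluation protocol.

## Difficulty labelling

The contextual label TD fuses three discretized screen-state variables.
Two conventions deserve note:

* **Entropy form.** The spatial entropy is the positive Shannon form
  H = −Σ p ln p in nats. The discretization thresholds (0.45 and 1)
  are only meaningful on this scale: the maximum over 8 zones is
  ln 8 ≈ 2.08, so all three states are reachable, whereas a base-10 or
  signed form would leave the "high" state empty. An empty screen is
  assigned H = 0 (minimal demand).
* **Interval convention.** An item is active on the half-open interval
  [t_appear, t_removed), so a removal instant is never double-counted.

Only one fusion rule is fixed by the design ("high iff N1 high, N2 high
and entropy ≥ medium"; with a binary N2 the "≥ medium" clause can only
mean "high"). The remaining cells follow the simplest monotone
completion: TD = 1 when at most one component is above its minimum,
TD = 2 otherwise. The full 18-cell table is exposed and overridable
(`rule_table` argument, YAML via the CLI), and a property test verifies
monotonicity: raising any component never lowers TD.

## Physiological features

* **SDNN** uses the sample (N−1) standard deviation over the most
  recent 300 heartbeats, emitted once 30 beats have accumulated and
  flagged `partial_window` until the window is full. The 30-beat
  warm-up trades a short unlabelled prefix against wildly unstable
  2-beat estimates; windows including the current beat (beat time ≤ t)
  are used.
* **Pupil cleansing** retains samples in [2, 8] mm inclusive; the
  artifact band is open at the boundaries.
* **z-normalization** moments come from the 5-min resting baseline
  processed by the *same* per-second pipeline, not from the session
  itself — the baseline is the calibration recording, and normalizing
  against it preserves load-related level shifts in the session.
* **Missing data** (pupil gaps, HRV warm-up) yields NaN rows that are
  dropped before modelling. Linear interpolation of interior gaps is
  available behind `interpolate=True` but is off by default: fabricating
  physiology is worse than losing seconds.

## Synthetic cohorts

The generator inverts the analysis assumptions: difficulty drives the
signals. Defaults describe one 25-min session (P1 2 min with no
stimuli, P2/P3 7 min, P4 9 min) for 17 retained participants with a
5-min resting baseline each.

* **Arrivals** are per-phase Poisson processes with exponential
  on-screen lifetimes (mean 60 s). Rates were chosen by occupancy
  arithmetic (mean count = rate × mean lifetime) so the phases span the
  discretization thresholds: targets (0, 3, 8, 14)/min give expected
  on-screen counts of roughly 3, 8 and 14 in P2–P4; messages
  (0, 1, 2, 4)/min give roughly 1, 2 and 4. Zone placement uses
  geometric weights with per-phase concentration (0.3, 0.4, 0.7, 1.0),
  from strongly clustered to uniform.
* **RR intervals**: per-beat Gaussian jitter with sd
  `rr_baseline_sd − sdnn_load_slope·(TD−1)` (floored at 1 ms) around a
  fixed 800 ms mean; defaults 50 ms baseline sd, 15 ms/step slope.
* **Pupil**: 60 Hz samples (typical of remote eye trackers;
  configurable) with mean `pupil_baseline + pupil_load_gain·(TD−1)`
  (defaults 4.5 mm, 0.35 mm/step), white noise (0.3 mm), a slow AR(1)
  drift emulating hippus (sd 0.12 mm, 10 s time constant), and
  artifacts injected with probability 0.02, drawn uniformly from
  [0.5, 2) ∪ (8, 10] mm so the cleansing filter removes exactly them.
* **Probes** every 90 s: the Likert answer equals the true TD with
  probability 0.8, else misses by one level; the ISA answer applies the
  same fidelity noise and then maps TD blocks into the 5-point scale
  (TD1→{1,2}, TD2→{2,3}, TD3→{4,5}, 65% weight on the lower level) so
  cohort contingency tables show the concordant-diagonal concentration
  typical of such validation tables. The Likert scale defaults to 5
  levels; both scale and rate are configurable since neither is fixed
  by the design.
* **Heterogeneity** scales the between-participant spread of baselines
  and load responses (relative sds 8–40% per parameter, clipped to
  physiological ranges). At 0 all participants are identical.

What the generator does **not** emulate: circadian and fatigue trends,
respiratory sinus arrhythmia structure in RR series, blink-driven pupil
dropouts, ectopic beats, learning effects across the session, and any
dependence of performance on state. Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it assumes — not
that real operators satisfy those assumptions.

## Classification protocol

Features enter the classifiers as baseline z-scores; no further scaling
is applied. SVMs use libsvm's native one-vs-one multiclass scheme, with
iterations capped at 20 000 — degree-3 polynomial kernels on strongly
overlapping classes otherwise stall the SMO solver without improving
the fit. Grid search evaluates every spec with fourfold stratified CV
on the training rows only; final accuracies come from the held-out 25%
(individual layer) or the 4 held-out participants (pooled layer). Grids
are ordered simplest-first (smallest k, fewest trees, smallest gamma)
and ties keep the earliest entry, making selection reproducible. The
grids cover k ∈ 1..25 across four distances, tree counts
{10, 23, 40, 68, 100}, and the three kernel families with
γ ∈ {0.1, 0.5, 1, 2}, coeff ∈ {0, 1}, degree ∈ {2, 3}. (Published
descriptions of these kernels sometimes swap the sigmoid and polynomial
formulas; the standard definitions are implemented.)

Per-class accuracy is the recall of that class; global accuracy is the
prior-weighted mean of recalls (asserted as an identity test). The
binary task merges TD1+TD2 into "low" against TD3 as "high" —
detecting the high-risk state is the operational goal; a
`drop_medium` scheme is available.

### Autocorrelation and the split design

Per-second rows are strongly autocorrelated: the SDNN window spans
minutes, so consecutive rows share almost all their beats, and pupil
drift is smooth. Under the standard stratified **random** 75/25 row
split, classifiers can match test rows to temporal neighbours in the
training set. This inflates within-subject accuracy even when the
physiological channels carry *no* load information: on a zero-coupling
cohort, random-split accuracy sits far above the majority-class rate
purely through temporal matching. The package therefore also offers a
contiguous **temporal block split** (first 75% train, last 25% test).
Under it the zero-coupling cohort shows no lift over the label-only
baseline — but its accuracy falls *below* the test-block majority rate,
because the block split shifts the class mix between train and test
(the final block is dominated by the hardest phase). The exact
"accuracy equals majority rate" calibration thus holds only for the
permuted-label control, which is also tested. Reported accuracies under
the random split should be read with this leakage caveat in mind; the
same caveat applies to any study using random row splits on 1 Hz
physiological features.

## Problem sizes

The acceptance script and heavy tests use 17-participant cohorts with
stratified row subsamples of 200–300 rows per participant for training,
which keeps grid search over all three method families to a few minutes
on one CPU while leaving hundreds of test rows per participant. The
probe-correlation replicate study draws 100 independent probe
realizations over a fixed cohort (16 probes × 17 participants = 272
pairs each).

## Known limitations

* The pooled layer's 13/4 participant split is a single random
  partition, as in the protocol it follows; accuracies at that layer
  inherit its variance.
* TD transitions propagate into SDNN with up to a 300-beat (~4 min)
  lag, so seconds near phase boundaries are systematically harder to
  classify from HRV alone.
* The contingency-table reconstruction from printed column percentages
  rounds each cell independently; derived column totals can differ from
  the printed ones by a few counts (197 vs 195 in the worked table),
  which is why the tau-b check carries a ±0.02 tolerance.
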