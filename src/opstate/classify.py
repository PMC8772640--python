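"""Supervised classification of operator functional state.

Three families of classifiers are tuned by exhaustive grid search with
fourfold cross-validation on the training rows and then evaluated on
held-out data:

* support-vector machines with RBF, sigmoid or polynomial kernels
  (multiclass handled one-vs-one),
* k-nearest neighbours under Euclidean, squared-Euclidean, Manhattan or
  Chebyshev distances,
* random forests with a tunable number of trees.

Features are the per-second z-scores ``(hrv_z, pd_z)``; labels are the
difficulty classes.  Reports carry global accuracy and per-class accuracy
(the recall of each class), matching the way such studies tabulate results.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import CV_FOLDS, binarize, make_splits

__all__ = [
    "KernelSpec", "KnnSpec", "ForestSpec", "Spec",
    "kernel_eval", "build_model", "train", "grid_search", "evaluate",
    "default_grid", "EvaluationReport", "IndividualSummary",
    "run_two_layer_experiment", "ExperimentResult",
    "FEATURES", "CLASS_NAMES",
]

FEATURES = ["hrv_z", "pd_z"]
CLASS_NAMES = {2: {1: "low", 2: "high"}, 3: {1: "low", 2: "medium", 3: "high"}}


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel: rbf exp(−γ‖u−v‖²), sigmoid tanh(γ·u'v + c), or
    polynomial (γ·u'v + c)^d."""

    family: str = "rbf"
    gamma: float = 1.0
    coeff: float = 0.0
    degree: int = 3

    def __post_init__(self):
        if self.family not in ("rbf", "sigmoid", "polynomial"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf" and self.gamma <= 0:
            raise ValueError("rbf gamma must be positive")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ValueError("degree must be a positive integer")


@dataclass(frozen=True)
class KnnSpec:
    """k-nearest-neighbour settings."""

    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in ("euclidean", "squared_euclidean", "manhattan", "chebyshev"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest settings."""

    n_trees: int = 68

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


Spec = Union[KernelSpec, KnnSpec, ForestSpec]


def kernel_eval(spec: KernelSpec, u: np.ndarray, v: np.ndarray) -> float:
    """Evaluate the kernel K(u, v) for one pair of vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have the same dimensionality")
    if spec.family == "rbf":
        return float(np.exp(-spec.gamma * np.sum((u - v) ** 2)))
    dot = float(u @ v)
    if spec.family == "sigmoid":
        return float(np.tanh(spec.gamma * dot + spec.coeff))
    return float((spec.gamma * dot + spec.coeff) ** spec.degree)


def build_model(spec: Spec, seed: int = 0):
    """Instantiate the sklearn estimator for a spec (unfitted)."""
    if isinstance(spec, KernelSpec):
        kernel = {"rbf": "rbf", "sigmoid": "sigmoid", "polynomial": "poly"}[spec.family]
        # SVC trains one-vs-one internally for multiclass problems.
        # Iterations are capped: high-degree polynomial kernels on
        # overlapping classes otherwise stall the SMO solver without
        # improving the solution.
        return SVC(kernel=kernel, gamma=spec.gamma, coef0=spec.coeff,
                   degree=spec.degree, random_state=seed, max_iter=20_000)
    if isinstance(spec, KnnSpec):
        if spec.metric == "squared_euclidean":
            return KNeighborsClassifier(n_neighbors=spec.k, metric="sqeuclidean",
                                        algorithm="brute")
        return KNeighborsClassifier(n_neighbors=spec.k, metric=spec.metric)
    if isinstance(spec, ForestSpec):
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=seed)
    raise TypeError(f"unknown spec type {type(spec)!r}")


def _xy(ds: pd.DataFrame):
    return ds[FEATURES].to_numpy(), ds["td"].to_numpy()


def train(ds: pd.DataFrame, spec: Spec, seed: int = 0):
    """Fit a classifier on a labelled dataset; requires ≥ 2 classes."""
    X, y = _xy(ds)
    if len(np.unique(y)) < 2:
        raise ValueError("training set holds a single class")
    return build_model(spec, seed).fit(X, y)


def grid_search(
    ds: pd.DataFrame,
    grid: Sequence[Spec],
    folds: int = CV_FOLDS,
    seed: int = 0,
) -> tuple[Spec, float]:
    """Exhaustive CV search over a spec grid.

    Returns the spec with the highest mean CV accuracy and that accuracy.
    Grids are ordered simplest-first and ties keep the earliest entry, so
    equal scores resolve to the simpler model.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    X, y = _xy(ds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_spec, best_score = None, -np.inf
    for spec in grid:
        score = cross_val_score(build_model(spec, seed), X, y, cv=cv).mean()
        if score > best_score:
            best_spec, best_score = spec, float(score)
    return best_spec, best_score


@dataclass
class EvaluationReport:
    """Accuracy of one fitted model on one test set."""

    global_accuracy: float
    per_class_accuracy: dict[str, float]   # recall of each class
    n_test: int
    best_spec: dict | None = None
    cv_accuracy: float | None = None

    def __post_init__(self):
        vals = [self.global_accuracy, *self.per_class_accuracy.values()]
        if any(not (0.0 <= v <= 1.0) for v in vals if not np.isnan(v)):
            raise ValueError("accuracies must lie in [0, 1]")


def evaluate(model, test: pd.DataFrame, n_classes: int | None = None) -> EvaluationReport:
    """Global accuracy and per-class recall on a held-out dataset."""
    if len(test) == 0:
        raise ValueError("empty test set")
    X, y = _xy(test)
    pred = model.predict(X)
    if n_classes is None:
        n_classes = 3 if 3 in np.unique(y) else 2
    names = CLASS_NAMES[n_classes]
    per_class = {}
    for code, name in names.items():
        mask = y == code
        per_class[name] = float((pred[mask] == code).mean()) if mask.any() else float("nan")
    return EvaluationReport(
        global_accuracy=float((pred == y).mean()),
        per_class_accuracy=per_class,
        n_test=int(len(y)),
    )


def default_grid(method: str) -> list[Spec]:
    """Search grids covering the settings such studies report as best.

    SVM: three kernel families with γ ∈ {0.1, 0.5, 1, 2}, coeff ∈ {0, 1},
    degree ∈ {2, 3}.  kNN: k ∈ 1..25 across four distances.  RF: tree
    counts {10, 23, 40, 68, 100}.
    """
    if method == "svm":
        grid: list[Spec] = []
        for gamma in (0.1, 0.5, 1.0, 2.0):
            grid.append(KernelSpec("rbf", gamma=gamma))
        for gamma in (0.1, 0.5, 1.0, 2.0):
            for coeff in (0.0, 1.0):
                grid.append(KernelSpec("sigmoid", gamma=gamma, coeff=coeff))
        for gamma in (0.1, 0.5, 1.0, 2.0):
            for coeff in (0.0, 1.0):
                for degree in (2, 3):
                    grid.append(KernelSpec("polynomial", gamma=gamma, coeff=coeff,
                                           degree=degree))
        return grid
    if method == "knn":
        return [KnnSpec(k=k, metric=m)
                for k in range(1, 26)
                for m in ("euclidean", "squared_euclidean", "manhattan", "chebyshev")]
    if method == "rf":
        return [ForestSpec(n_trees=n) for n in (10, 23, 40, 68, 100)]
    raise ValueError(f"unknown method {method!r}")


@dataclass
class IndividualSummary:
    """Across-participant aggregate of individual-layer accuracies."""

    mean: float
    sd: float
    min: float
    max: float
    per_participant: dict[str, EvaluationReport]


@dataclass
class ExperimentResult:
    """All reports of one two-layer run, keyed (layer, method, n_classes)."""

    pooled: dict[tuple[str, int], EvaluationReport]
    individual: dict[tuple[str, int], IndividualSummary]
    seed: int


def _stratified_subsample(ds: pd.DataFrame, max_rows: int | None,
                          rng: np.random.Generator) -> pd.DataFrame:
    if max_rows is None or len(ds) <= max_rows:
        return ds
    frac = max_rows / len(ds)
    parts = [g.sample(n=max(1, int(round(frac * len(g)))),
                      random_state=int(rng.integers(0, 2**31 - 1)))
             for _, g in ds.groupby("td")]
    return pd.concat(parts).sort_index().reset_index(drop=True)


def run_two_layer_experiment(
    datasets: list[pd.DataFrame],
    methods: Iterable[str] = ("svm", "knn", "rf"),
    grids: dict[str, Sequence[Spec]] | None = None,
    seed: int = 0,
    class_tasks: Iterable[int] = (3, 2),
    max_rows_per_participant: int | None = None,
    binarize_scheme: str = "merge_low",
    temporal_split: bool = False,
) -> ExperimentResult:
    """Run the full two-layer, two-task evaluation protocol.

    ``datasets`` holds one labelled 3-class dataset per participant.
    For each task (3-class and binary) and each method, the pooled layer
    trains on 13/17 of the participants and tests on the rest, and the
    individual layer runs a stratified 75/25 split per participant;
    hyperparameters come from fourfold-CV grid search on each training
    set.  ``max_rows_per_participant`` optionally subsamples rows
    (stratified, seeded) to bound runtime on large cohorts;
    ``temporal_split=True`` switches the individual layer to the
    leakage-free contiguous block split (see
    :func:`opstate.datasets.make_splits`).
    """
    grids = grids or {}
    rng = np.random.default_rng(seed)
    participants = [str(ds["participant"].iloc[0]) for ds in datasets]

    pooled_reports: dict[tuple[str, int], EvaluationReport] = {}
    individual_reports: dict[tuple[str, int], IndividualSummary] = {}

    for n_classes in class_tasks:
        task_ds = [ds if n_classes == 3 else binarize(ds, binarize_scheme)
                   for ds in datasets]
        task_ds = [_stratified_subsample(ds, max_rows_per_participant, rng)
                   for ds in task_ds]
        by_participant = dict(zip(participants, task_ds))

        plan = make_splits(participants, "pooled", seed=int(rng.integers(0, 2**31 - 1)))
        train_df = pd.concat([by_participant[p] for p in plan.train_participants],
                             ignore_index=True)
        test_df = pd.concat([by_participant[p] for p in plan.test_participants],
                            ignore_index=True)

        for method in methods:
            grid = grids.get(method, default_grid(method))
            gs_seed = int(rng.integers(0, 2**31 - 1))
            spec, cv_acc = grid_search(train_df, grid, seed=gs_seed)
            model = train(train_df, spec, seed=gs_seed)
            rep = evaluate(model, test_df, n_classes=n_classes)
            rep.best_spec = asdict(spec)
            rep.cv_accuracy = cv_acc
            pooled_reports[(method, n_classes)] = rep

            per_part: dict[str, EvaluationReport] = {}
            for p, ds in by_participant.items():
                sp_seed = int(rng.integers(0, 2**31 - 1))
                iplan = make_splits(ds, "individual", seed=sp_seed,
                                    temporal=temporal_split)
                tr = ds.iloc[iplan.train_index]
                te = ds.iloc[iplan.test_index]
                ispec, icv = grid_search(tr, grid, seed=sp_seed)
                irep = evaluate(train(tr, ispec, seed=sp_seed), te, n_classes=n_classes)
                irep.best_spec = asdict(ispec)
                irep.cv_accuracy = icv
                per_part[p] = irep
            accs = np.array([r.global_accuracy for r in per_part.values()])
            individual_reports[(method, n_classes)] = IndividualSummary(
                mean=float(accs.mean()), sd=float(accs.std(ddof=1)),
                min=float(accs.min()), max=float(accs.max()),
                per_participant=per_part,
            )
    return ExperimentResult(pooled=pooled_reports, individual=individual_reports,
                            seed=seed)
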