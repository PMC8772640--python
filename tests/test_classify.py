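"""Classifier construction, kernel math, grid search and evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics.pairwise import polynomial_kernel, rbf_kernel, sigmoid_kernel

from opstate.classify import (
    ForestSpec,
    KernelSpec,
    KnnSpec,
    build_model,
    evaluate,
    grid_search,
    kernel_eval,
    train,
)


def blob_dataset(centers, n_per=120, sd=0.2, seed=0, participant="P01"):
    rng = np.random.default_rng(seed)
    rows = []
    for label, (cx, cy) in centers.items():
        rows.append(pd.DataFrame({
            "participant": participant,
            "t_s": 0.0,
            "hrv_z": rng.normal(cx, sd, n_per),
            "pd_z": rng.normal(cy, sd, n_per),
            "td": label,
        }))
    ds = pd.concat(rows, ignore_index=True)
    ds["t_s"] = np.arange(float(len(ds)))
    return ds


THREE_BLOBS = {1: (0.0, 0.0), 2: (3.0, 0.0), 3: (0.0, 3.0)}


class TestKernelEval:
    def test_rbf_identity(self):
        spec = KernelSpec("rbf", gamma=0.7)
        assert kernel_eval(spec, np.ones(3), np.ones(3)) == 1.0

    def test_sigmoid_at_origin(self):
        spec = KernelSpec("sigmoid", gamma=0.5, coeff=0.0)
        assert kernel_eval(spec, np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_polynomial_hand_example(self):
        spec = KernelSpec("polynomial", gamma=1.0, coeff=1.0, degree=2)
        assert kernel_eval(spec, np.array([1.0, 1.0]), np.array([1.0, 1.0])) == 9.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec(), np.ones(2), np.ones(3))

    def test_matches_sklearn_pairwise_kernels(self, rng):
        for _ in range(100):
            u = rng.normal(size=3)
            v = rng.normal(size=3)
            gamma = float(rng.uniform(0.1, 2.0))
            coeff = float(rng.uniform(-1, 1))
            d = int(rng.integers(1, 4))
            U, V = u[None], v[None]
            assert kernel_eval(KernelSpec("rbf", gamma), u, v) == pytest.approx(
                rbf_kernel(U, V, gamma=gamma)[0, 0])
            assert kernel_eval(KernelSpec("sigmoid", gamma, coeff), u, v) == pytest.approx(
                sigmoid_kernel(U, V, gamma=gamma, coef0=coeff)[0, 0])
            assert kernel_eval(
                KernelSpec("polynomial", gamma, coeff, d), u, v
            ) == pytest.approx(
                polynomial_kernel(U, V, degree=d, gamma=gamma, coef0=coeff)[0, 0])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("linear")
        with pytest.raises(ValueError):
            KernelSpec("rbf", gamma=-1.0)
        with pytest.raises(ValueError):
            KnnSpec(k=0)
        with pytest.raises(ValueError):
            ForestSpec(n_trees=0)


class TestTrain:
    def test_knn_k1_memorizes_training_set(self):
        ds = blob_dataset(THREE_BLOBS, seed=1)
        model = train(ds, KnnSpec(k=1, metric="chebyshev"))
        rep = evaluate(model, ds)
        assert rep.global_accuracy == 1.0

    def test_svm_separates_blobs(self):
        tr = blob_dataset({1: (0.0, 0.0), 2: (4.0, 4.0)}, seed=2)
        te = blob_dataset({1: (0.0, 0.0), 2: (4.0, 4.0)}, seed=3)
        model = train(tr, KernelSpec("rbf", gamma=0.5))
        assert evaluate(model, te, n_classes=2).global_accuracy == 1.0

    def test_single_class_rejected(self):
        ds = blob_dataset({2: (0.0, 0.0)}, seed=4)
        with pytest.raises(ValueError):
            train(ds, KnnSpec())

    def test_forest_averaging_stabilizes_accuracy(self):
        tr = blob_dataset(THREE_BLOBS, sd=1.2, seed=5)
        te = blob_dataset(THREE_BLOBS, sd=1.2, seed=6)
        accs = {n: [] for n in (1, 68)}
        for n in accs:
            for seed in range(10):
                accs[n].append(
                    evaluate(train(tr, ForestSpec(n), seed=seed), te).global_accuracy)
        assert np.std(accs[68]) < np.std(accs[1])

    def test_deterministic_given_seed(self):
        ds = blob_dataset(THREE_BLOBS, sd=1.0, seed=7)
        te = blob_dataset(THREE_BLOBS, sd=1.0, seed=8)
        r1 = evaluate(train(ds, ForestSpec(25), seed=3), te)
        r2 = evaluate(train(ds, ForestSpec(25), seed=3), te)
        assert r1 == r2


class TestGridSearch:
    def test_singleton_grid(self):
        ds = blob_dataset(THREE_BLOBS, seed=9)
        spec, acc = grid_search(ds, [KnnSpec(k=3)])
        assert spec == KnnSpec(k=3)
        assert 0.0 <= acc <= 1.0

    def test_selects_adequate_model_for_separable_data(self):
        ds = blob_dataset(THREE_BLOBS, seed=10)
        grid = [KnnSpec(k=1), KnnSpec(k=5), KnnSpec(k=200)]
        spec, acc = grid_search(ds, grid, seed=1)
        assert spec.k < 200  # k of 200 underfits 120-point classes
        assert acc > 0.95

    def test_best_is_argmax_over_grid(self):
        ds = blob_dataset(THREE_BLOBS, sd=1.5, seed=11)
        grid = [KnnSpec(k=k) for k in (1, 5, 15)]
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        best, best_acc = grid_search(ds, grid, seed=2)
        X = ds[["hrv_z", "pd_z"]].to_numpy()
        y = ds["td"].to_numpy()
        cv = StratifiedKFold(4, shuffle=True, random_state=2)
        scores = [cross_val_score(build_model(s, 2), X, y, cv=cv).mean() for s in grid]
        assert best_acc == pytest.approx(max(scores))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(blob_dataset(THREE_BLOBS), [])


class TestEvaluate:
    def test_constant_predictor_confusion_arithmetic(self):
        te = blob_dataset(THREE_BLOBS, n_per=10, seed=12)

        class Always3:
            def predict(self, X):
                return np.full(len(X), 3)

        rep = evaluate(Always3(), te)
        assert rep.global_accuracy == pytest.approx(1 / 3)
        assert rep.per_class_accuracy == {"low": 0.0, "medium": 0.0, "high": 1.0}

    def test_global_is_prior_weighted_recall(self):
        tr = blob_dataset(THREE_BLOBS, sd=1.5, seed=13)
        te = blob_dataset({1: (0, 0), 2: (3, 0), 3: (0, 3)}, n_per=50, sd=1.5, seed=14)
        rep = evaluate(train(tr, KnnSpec(k=5)), te)
        y = te["td"].to_numpy()
        weights = {c: (y == code).mean()
                   for code, c in zip((1, 2, 3), ("low", "medium", "high"))}
        weighted = sum(weights[c] * rep.per_class_accuracy[c] for c in weights)
        assert rep.global_accuracy == pytest.approx(weighted)

    def test_empty_test_rejected(self):
        ds = blob_dataset(THREE_BLOBS, seed=15)
        model = train(ds, KnnSpec(k=1))
        with pytest.raises(ValueError):
            evaluate(model, ds.iloc[:0])

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(16)
        ds = blob_dataset(THREE_BLOBS, n_per=150, seed=16)
        shuffled = ds.copy()
        shuffled["td"] = rng.permutation(shuffled["td"].to_numpy())
        tr = shuffled.iloc[:300]
        te = shuffled.iloc[300:]
        for spec in (KernelSpec("rbf", 1.0), KnnSpec(k=15), ForestSpec(40)):
            acc = evaluate(train(tr, spec, seed=1), te).global_accuracy
            # majority rate is ~1/3; binomial noise on 150 test rows
            assert acc < 1 / 3 + 4 * np.sqrt((1 / 3) * (2 / 3) / len(te))
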