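"""Hierarchical SVM, cross-validation, ROC/AUC and leakage guards."""

import numpy as np
import pytest

from gaussmap.classify import (ClassifierConfig, InsufficientClassesError,
                               MatrixDataset, cross_validate,
                               predict_hierarchical, roc_curve,
                               train_hierarchical)

FAST = ClassifierConfig(C_grid=(1.0, 10.0), gamma_scale=(1.0,),
                        k_grid=(None,), inner_folds=2, folds=3, repeats=1)


def blobs(n_per_class=8, sep=6.0, d=4, seed=0, labels=("NC", "MCI", "AD")):
    """Well-separated Gaussian clusters, one per diagnostic class."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, lab in enumerate(labels):
        mu = np.zeros(d)
        mu[i % d] = sep * (i + 1)
        X.append(rng.normal(size=(n_per_class, d)) + mu)
        y += [lab] * n_per_class
    return np.vstack(X), np.array(y)


def pairwise_auc(scores, truth):
    """Brute-force Mann-Whitney: wins + half-ties over all pos/neg pairs."""
    pos = np.asarray(scores)[np.asarray(truth) == 1]
    neg = np.asarray(scores)[np.asarray(truth) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        pts, auc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_constant_scores_give_chance(self):
        pts, auc = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_worked_pairwise_example(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 wins of 4 pairs
        _, auc = roc_curve([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_equals_pairwise_count_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(6, 30)
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            scores = np.round(rng.normal(size=n), 1)  # force ties sometimes
            _, auc = roc_curve(scores, truth)
            assert auc == pytest.approx(pairwise_auc(scores, truth),
                                        abs=1e-9)

    def test_monotone_roc_points(self):
        rng = np.random.default_rng(3)
        pts, _ = roc_curve(rng.normal(size=40), rng.integers(0, 2, size=40))
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestHierarchicalModel:
    def test_separable_data_trains_to_perfection(self):
        X, y = blobs(n_per_class=8, sep=8.0)
        model = train_hierarchical(X, y, FAST, seed=0)
        pred, dv1, dv2 = predict_hierarchical(model, X)
        assert (pred == y).all()

    def test_hierarchy_short_circuits_to_nc(self):
        X, y = blobs(n_per_class=8, sep=8.0)
        model = train_hierarchical(X, y, FAST, seed=0)
        nc_like = X[y == "NC"]
        pred, dv1, _ = predict_hierarchical(model, nc_like)
        assert (dv1 < 0).all() and (pred == "NC").all()

    def test_abnormal_splits_by_stage2(self):
        X, y = blobs(n_per_class=8, sep=8.0)
        model = train_hierarchical(X, y, FAST, seed=0)
        pred, dv1, dv2 = predict_hierarchical(model, X[y != "NC"])
        assert (dv1 >= 0).all()
        assert set(pred) == {"MCI", "AD"}

    def test_boundary_tie_breaks_abnormal(self):
        X, y = blobs(n_per_class=8, sep=8.0)
        model = train_hierarchical(X, y, FAST, seed=0)

        class ZeroStage:
            def decision_function(self, X):
                return np.zeros(len(X))
        model.stage1 = ZeroStage()
        pred, _, _ = predict_hierarchical(model, X[:3])
        assert (pred != "NC").all()

    def test_missing_class_rejected(self):
        X, y = blobs(labels=("NC", "MCI"))
        with pytest.raises(InsufficientClassesError):
            train_hierarchical(X, y, FAST)


class TestCrossValidate:
    def test_separable_cohort_reaches_perfect_accuracy(self):
        X, y = blobs(n_per_class=9, sep=10.0)
        res = cross_validate(MatrixDataset(X, y), FAST, seed=0)
        assert res.overall_accuracy == 1.0
        assert res.stage1.accuracy == 1.0 and res.stage2.accuracy == 1.0

    def test_same_seed_is_bit_identical(self):
        X, y = blobs(n_per_class=7, sep=3.0, seed=4)
        r1 = cross_validate(MatrixDataset(X, y), FAST, seed=5)
        r2 = cross_validate(MatrixDataset(X, y), FAST, seed=5)
        assert r1.overall_accuracy == r2.overall_accuracy
        assert r1.stage1.to_dict() == r2.stage1.to_dict()
        assert r1.stage2.to_dict() == r2.stage2.to_dict()

    def test_overall_errors_at_least_stage1_errors(self):
        # hierarchy error composition: any stage-1 miss is an overall miss
        X, y = blobs(n_per_class=8, sep=1.5, seed=2)  # deliberately hard
        res = cross_validate(MatrixDataset(X, y), FAST, seed=1)
        stage1_errors = res.stage1.fp + res.stage1.fn
        n = len(y)
        overall_errors = round((1 - res.overall_accuracy) * n)
        assert overall_errors >= stage1_errors

    def test_report_confusion_identities(self):
        X, y = blobs(n_per_class=8, sep=2.0, seed=3)
        res = cross_validate(MatrixDataset(X, y), FAST, seed=2)
        for rep in (res.stage1, res.stage2):
            tot = rep.tp + rep.tn + rep.fp + rep.fn
            assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / tot)
            assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
            assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
            # AUC is the trapezoid under its own ROC points
            x, t = rep.roc_points[:, 0], rep.roc_points[:, 1]
            assert rep.auc == pytest.approx(np.trapezoid(t, x), abs=1e-9)

    def test_class_too_small_for_folds(self):
        X, y = blobs(n_per_class=3)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(MatrixDataset(X, y),
                           ClassifierConfig(folds=5, repeats=1), seed=0)

    def test_leakage_canary(self):
        # a feature equal to the class identity must be learnable...
        rng = np.random.default_rng(9)
        n = 12
        y = np.array(["NC"] * n + ["MCI"] * n + ["AD"] * n)
        X = rng.normal(size=(3 * n, 6))
        X[:, 0] = (y != "NC") * 2.0 + (y == "AD") * 4.0
        cfg = ClassifierConfig(C_grid=(1.0, 10.0), gamma_scale=(1.0,),
                               k_grid=(1, None), inner_folds=2, folds=3,
                               repeats=1)
        res = cross_validate(MatrixDataset(X, y), cfg, seed=3)
        assert res.overall_accuracy >= 0.95
        # ...and the same column shuffled must carry no signal
        Xs = X.copy()
        Xs[:, 0] = rng.permutation(Xs[:, 0])
        res_null = cross_validate(MatrixDataset(Xs, y), cfg, seed=3)
        assert res_null.overall_accuracy < 0.6
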