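"""Kernels, SVM solution properties (KKT), CV bookkeeping, and the MLP."""

import numpy as np
import pytest

from emgstress import classify
from emgstress.classify import (
    CVConfig,
    DegenerateDataError,
    KernelSpec,
    MLPStressClassifier,
    SVMStressClassifier,
    confusion_metrics,
    crossvalidate,
    kernel_grid,
    make_kernel,
)


def two_clusters(n_per_class=25, separation=10.0, seed=0):
    """Linearly separable 2-D toy: two Gaussian blobs `separation` apart."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, (n_per_class, 2))
    X1 = rng.normal(separation, 1.0, (n_per_class, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestKernels:
    def test_linear_is_the_dot_product(self):
        K = make_kernel(KernelSpec("linear"))
        assert K(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]))[0, 0] == 11.0

    def test_quadratic_and_cubic_are_inhomogeneous_polynomials(self):
        u = np.array([[1.0, 0.0]])
        assert make_kernel(KernelSpec("quadratic"))(u, u)[0, 0] == 4.0  # (1+1)^2
        assert make_kernel(KernelSpec("cubic"))(u, u)[0, 0] == 8.0  # (1+1)^3

    def test_gaussian_is_one_on_the_diagonal(self):
        K = make_kernel(KernelSpec("gaussian", scale=1.7))
        U = np.random.default_rng(0).normal(0, 3, (5, 2))
        np.testing.assert_allclose(np.diag(K(U, U)), 1.0)

    def test_gaussian_value(self):
        K = make_kernel(KernelSpec("gaussian", scale=2.0))
        u, v = np.array([[0.0, 0.0]]), np.array([[2.0, 0.0]])
        assert K(u, v)[0, 0] == pytest.approx(np.exp(-1.0))

    def test_bandwidth_presets_from_predictor_count(self):
        grid = kernel_grid(P=2)
        root = np.sqrt(2.0)
        assert grid["fine_gaussian"].scale == pytest.approx(root / 4)
        assert grid["medium_gaussian"].scale == pytest.approx(root)
        assert grid["coarse_gaussian"].scale == pytest.approx(4 * root)

    def test_literal_bandwidth_convention(self):
        grid = kernel_grid(P=2, convention="literal")
        assert grid["fine_gaussian"].scale == pytest.approx(0.5)
        assert grid["medium_gaussian"].scale == pytest.approx(2.0)
        assert grid["coarse_gaussian"].scale == pytest.approx(8.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("septic")
        with pytest.raises(ValueError):
            KernelSpec("gaussian", scale=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("linear", P=0)


class TestTrainSvm:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = two_clusters()
        model = classify.train_svm(X, y, KernelSpec("linear"))
        # brute-force check: every point is on its own side of the boundary
        scores = model.decision_function(X)
        assert np.all(np.sign(scores) == np.where(y == 1, 1.0, -1.0))
        assert np.array_equal(model.predict(X), y)

    def test_free_support_vectors_sit_on_the_margin(self):
        # KKT: unbounded support vectors (0 < |alpha| < C) have decision +-1
        X, y = two_clusters(separation=4.0, seed=3)
        model = classify.train_svm(X, y, KernelSpec("linear"), box_constraint=10.0)
        alphas = np.abs(model.dual_coef_[0])
        free = alphas < 10.0 - 1e-8
        assert free.any()
        sv_scores = model.decision_function(X[model.support_])
        np.testing.assert_allclose(np.abs(sv_scores[free]), 1.0, atol=1e-4)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            classify.train_svm(X, np.zeros(10, dtype=int), KernelSpec("linear"))

    def test_identical_point_sets_in_both_classes_rejected(self):
        X0 = np.random.default_rng(1).normal(0, 1, (8, 2))
        X = np.vstack([X0, X0])
        y = np.array([0] * 8 + [1] * 8)
        with pytest.raises(DegenerateDataError):
            classify.train_svm(X, y, KernelSpec("cubic"))


class TestConfusionMetrics:
    def test_direct_evaluation(self):
        m = confusion_metrics(tp=40, fn=0, tn=9, fp=1)
        assert m["accuracy"] == pytest.approx(98.0)
        assert m["sensitivity"] == pytest.approx(100.0)
        assert m["specificity"] == pytest.approx(90.0)


class TestCrossvalidate:
    def test_separable_data_scores_perfectly(self):
        X, y = two_clusters()
        report = crossvalidate(
            lambda: SVMStressClassifier(KernelSpec("cubic")),
            X, y, CVConfig(k=10, seed=0),
        )
        assert report.accuracy == 100.0
        assert report.auc == 1.0
        assert report.sensitivity == 100.0 and report.specificity == 100.0

    def test_every_sample_validated_exactly_once(self):
        X, y = two_clusters(n_per_class=20)
        report = crossvalidate(
            lambda: SVMStressClassifier(KernelSpec("linear")), X, y,
            CVConfig(k=5, seed=1),
        )
        pooled = report.pooled
        assert pooled.tp + pooled.fn + pooled.tn + pooled.fp == y.size
        assert len(report.folds) == 5
        sizes = [f.tp + f.fn + f.tn + f.fp for f in report.folds]
        assert all(s == 8 for s in sizes)  # stratified: 4 + 4 per fold

    def test_fold_class_balance_within_one_sample(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (50, 2))
        y = np.array([0] * 10 + [1] * 40)
        report = crossvalidate(
            lambda: SVMStressClassifier(KernelSpec("linear")), X, y,
            CVConfig(k=10, seed=0),
        )
        for f in report.folds:
            assert f.tn + f.fp == 1  # one rest sample per fold
            assert f.tp + f.fn == 4

    def test_mean_fold_accuracy_matches_confusions(self):
        X, y = two_clusters(separation=1.0, seed=5)  # overlapping clusters
        report = crossvalidate(
            lambda: SVMStressClassifier(KernelSpec("linear")), X, y,
            CVConfig(k=10, seed=3),
        )
        recomputed = 100.0 * np.mean([f.accuracy for f in report.folds])
        assert report.accuracy == pytest.approx(recomputed, abs=1e-12)

    def test_oversized_k_rejected(self):
        X, y = two_clusters(n_per_class=4)
        with pytest.raises(ValueError, match="exceeds"):
            crossvalidate(
                lambda: SVMStressClassifier(KernelSpec("linear")), X, y,
                CVConfig(k=5, seed=0),
            )

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            CVConfig(k=1)


class TestMlp:
    def test_separable_toy_cross_validates_above_95_percent(self):
        X, y = two_clusters()
        report = crossvalidate(
            lambda: MLPStressClassifier(hidden=10, seed=0), X, y,
            CVConfig(k=10, seed=0),
        )
        assert report.accuracy >= 95.0

    def test_seeded_training_is_deterministic(self):
        X, y = two_clusters(separation=2.0)
        a = MLPStressClassifier(hidden=10, seed=11).fit(X, y)
        b = MLPStressClassifier(hidden=10, seed=11).fit(X, y)
        np.testing.assert_array_equal(a.theta_, b.theta_)

    def test_constant_features_predict_the_majority_class(self):
        X = np.ones((50, 2))
        y = np.array([0] * 10 + [1] * 40)
        model = MLPStressClassifier(hidden=10, seed=0).fit(X, y)
        pred = model.predict(X)
        assert np.all(pred == 1)  # SC is the 80% majority
        assert np.mean(pred == y) == pytest.approx(0.8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            MLPStressClassifier(seed=0).fit(X, np.ones(10, dtype=int))
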