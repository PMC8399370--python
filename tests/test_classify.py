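"""Classifier bench: splits, kernel, CV protocol and the metric layer."""

import warnings

import numpy as np
import pytest

from afdet.classify import (
    AF,
    NON_AF,
    EvalReport,
    GksvmParams,
    LabeledDataset,
    cross_validate,
    evaluate,
    gaussian_kernel,
    stratified_split,
    train_model,
    tune_hyperparameters,
)


def gaussian_clouds(n_per_class=20, dim=2, separation=6.0, seed=0) -> LabeledDataset:
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per_class, dim))
    b = rng.normal(separation, 1, (n_per_class, dim))
    return LabeledDataset(
        features=np.vstack([a, b]),
        labels=np.array([AF] * n_per_class + [NON_AF] * n_per_class),
    )


class TestStratifiedSplit:
    def test_exact_stratification(self):
        data = gaussian_clouds(100)
        split = stratified_split(data, test_fraction=0.1, seed=0)
        test = split.test
        assert np.sum(test.labels == AF) == 10
        assert np.sum(test.labels == NON_AF) == 10

    def test_deterministic(self):
        data = gaussian_clouds(50)
        a = stratified_split(data, 0.1, seed=3)
        b = stratified_split(data, 0.1, seed=3)
        np.testing.assert_array_equal(a.split_tags, b.split_tags)

    def test_single_class_rejected(self):
        data = LabeledDataset(np.zeros((10, 2)), np.array([AF] * 10))
        with pytest.raises(ValueError):
            stratified_split(data, 0.1, seed=0)


class TestGaussianKernel:
    def test_identity_and_closed_form(self):
        x = np.arange(5.0)
        assert gaussian_kernel(x, x) == 1.0
        y = x + np.array([3.0, 0, 0, 0, 4.0])  # ||x-y|| = 5
        assert gaussian_kernel(x, y, scale=5.0) == pytest.approx(np.exp(-1.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.ones(3), np.ones(4))

    def test_gram_matrix_psd_and_symmetric(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 10, (15, 4))
        G = np.array([[gaussian_kernel(a, b, 7.0) for b in pts] for a in pts])
        np.testing.assert_allclose(G, G.T)
        assert np.all(G > 0) and np.all(G <= 1)
        assert np.min(np.linalg.eigvalsh(G)) >= -1e-8


class TestTrainModel:
    def test_gksvm_separates_clouds(self):
        data = gaussian_clouds()
        model = train_model("gksvm", data)
        report = evaluate(model, data)
        assert report.accuracy == 1.0

    def test_knn_self_prediction(self):
        # correlation distance needs enough dimensions to be informative
        data = gaussian_clouds(dim=10)
        model = train_model("knn", data)
        assert np.all(model.predict(data.features) == data.labels)

    def test_naive_bayes_on_separated_gaussians(self):
        train = gaussian_clouds(100, separation=6.0, seed=1)
        test = gaussian_clouds(100, separation=6.0, seed=2)
        model = train_model("naive_bayes", train)
        assert evaluate(model, test).accuracy >= 0.99

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            train_model("random_forest", gaussian_clouds())

    def test_single_class_rejected(self):
        data = LabeledDataset(np.zeros((4, 2)), np.array([AF] * 4))
        with pytest.raises(ValueError):
            train_model("gksvm", data)


class TestCrossValidate:
    def test_separable_data_perfect_cv(self):
        data = gaussian_clouds(50)
        assert cross_validate("gksvm", data, folds=10, seed=0) == 1.0

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(12)
        data = gaussian_clouds(200, separation=6.0, seed=12)
        permuted = LabeledDataset(data.features, rng.permutation(data.labels))
        acc = cross_validate("gksvm", permuted, folds=10, seed=0)
        assert 0.4 <= acc <= 0.6

    def test_small_class_rejected(self):
        data = gaussian_clouds(5)
        with pytest.raises(ValueError):
            cross_validate("gksvm", data, folds=10, seed=0)


class TestTuneHyperparameters:
    def test_single_iteration_returns_evaluated_config(self):
        data = gaussian_clouds(30)
        params, acc = tune_hyperparameters("gksvm", data, iterations=1, seed=0, folds=5)
        assert isinstance(params, GksvmParams)
        assert 0.0 <= acc <= 1.0

    def test_best_of_n_dominates_first_draw(self):
        data = gaussian_clouds(30, separation=2.0, seed=5)
        _, acc1 = tune_hyperparameters("gksvm", data, iterations=1, seed=7, folds=5)
        _, acc10 = tune_hyperparameters("gksvm", data, iterations=10, seed=7, folds=5)
        assert acc10 >= acc1


class TestEvaluate:
    def test_all_correct(self):
        data = gaussian_clouds(dim=10)
        model = train_model("knn", data)
        r = evaluate(model, data)
        assert (r.accuracy, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        r = EvalReport(tp=3, fp=1, tn=4, fn=2)
        assert r.accuracy == pytest.approx(0.7)
        assert r.sensitivity == pytest.approx(0.6)
        assert r.specificity == pytest.approx(0.8)

    def test_undefined_sensitivity_is_nan_with_warning(self):
        r = EvalReport(tp=0, fp=0, tn=5, fn=0)
        with pytest.warns(UserWarning):
            assert np.isnan(r.sensitivity)
        assert r.specificity == 1.0

    def test_weighted_accuracy_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            r = EvalReport(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            p, n = tp + fn, tn + fp
            weighted = (r.sensitivity * p + r.specificity * n) / (p + n)
            assert r.accuracy == pytest.approx(weighted)

    def test_label_swap_symmetry(self):
        r = EvalReport(tp=3, fp=1, tn=4, fn=2)
        swapped = EvalReport(tp=r.tn, fp=r.fn, tn=r.tp, fn=r.fp)
        assert swapped.sensitivity == r.specificity
        assert swapped.specificity == r.sensitivity
        assert swapped.accuracy == r.accuracy

    def test_empty_test_rejected(self):
        model = train_model("knn", gaussian_clouds(dim=10))
        empty = LabeledDataset(np.empty((0, 2)), np.empty(0, dtype=str))
        with pytest.raises(ValueError):
            evaluate(model, empty)
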