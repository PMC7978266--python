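"""Feature assembly, stratified split, standardization, models, evaluation."""

import numpy as np
import pytest

from leafsense.classify import (
    FEATURE_NAMES,
    N_FEATURES,
    assemble_features,
    apply_standardizer,
    cross_validate,
    evaluate,
    fit_standardizer,
    stratified_split,
    train_ann,
    train_svm,
)
from leafsense.colorfeat import ColorFeatureVector
from leafsense.errors import ConfigError
from leafsense.localfeat import LocalFeatureVector
from leafsense.mlp import MLPFreshnessClassifier
from leafsense.panel import coarsen


def _blobs(rng, n_per_class=40, n_classes=4, d=10, sep=6.0):
    X, y = [], []
    for c in range(n_classes):
        X.append(rng.normal(c * sep, 1.0, size=(n_per_class, d)))
        y.append(np.full(n_per_class, c + 1))
    return np.concatenate(X), np.concatenate(y)


class TestAssemble:
    def test_layout_230(self, rng):
        color = ColorFeatureVector(rng.random(30), image_id="a")
        local = LocalFeatureVector(rng.random(200), np.zeros(10), image_id="a")
        fv = assemble_features(color, local)
        assert fv.values.shape == (N_FEATURES,) == (230,)
        np.testing.assert_array_equal(fv.values[:30], color.values)
        np.testing.assert_array_equal(fv.values[30:], local.values)
        assert len(FEATURE_NAMES) == 230
        assert FEATURE_NAMES[0] == "gray_mean" and FEATURE_NAMES[30] == "c0_k00"

    def test_id_mismatch_rejected(self, rng):
        color = ColorFeatureVector(rng.random(30), image_id="a")
        local = LocalFeatureVector(rng.random(200), np.zeros(10), image_id="b")
        with pytest.raises(ConfigError, match="mismatch"):
            assemble_features(color, local)


class TestStratifiedSplit:
    def test_study_scale_arithmetic(self):
        # 1,045 items with the study's class imbalance -> 836 train / 209 test
        labels = np.repeat([1, 2, 3, 4], [172, 373, 452, 48])
        plan = stratified_split(labels, 0.2, seed=0)
        assert plan.train_idx.size == 836
        assert plan.test_idx.size == 209
        assert np.intersect1d(plan.train_idx, plan.test_idx).size == 0
        # per-class proportions within one image of 20%
        for cls, n_cls in zip([1, 2, 3, 4], [172, 373, 452, 48]):
            n_test = (labels[plan.test_idx] == cls).sum()
            assert abs(n_test - 0.2 * n_cls) <= 1

    def test_small_balanced_case(self):
        labels = np.array([1] * 5 + [2] * 5)
        plan = stratified_split(labels, 0.2, seed=3)
        assert plan.test_idx.size == 2
        assert set(labels[plan.test_idx]) == {1, 2}

    def test_singleton_class_goes_to_training(self):
        labels = np.array([1] * 8 + [2])
        with pytest.warns(UserWarning, match="< 2 members"):
            plan = stratified_split(labels, 0.2, seed=0)
        assert 8 in plan.train_idx  # the lone class-2 item

    def test_empty_labels_rejected(self):
        with pytest.raises(ConfigError):
            stratified_split(np.array([]), 0.2, seed=0)

    def test_seeded_determinism(self):
        labels = np.repeat([1, 2, 3, 4], 25)
        p1 = stratified_split(labels, 0.2, seed=9)
        p2 = stratified_split(labels, 0.2, seed=9)
        np.testing.assert_array_equal(p1.test_idx, p2.test_idx)


class TestStandardizer:
    def test_population_z_scores(self):
        s = fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
        out = apply_standardizer(s, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)

    def test_constant_column_passes_through_as_zeros(self):
        s = fit_standardizer(np.full((5, 1), 4.0))
        out = apply_standardizer(s, np.full((3, 1), 4.0))
        assert (out == 0.0).all()

    def test_test_value_at_training_mean_maps_to_zero(self):
        s = fit_standardizer(np.array([[0.0], [10.0]]))
        assert apply_standardizer(s, np.array([[5.0]]))[0, 0] == 0.0


class TestSvm:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X, y = _blobs(rng, n_classes=2)
        s = fit_standardizer(X)
        model = train_svm(apply_standardizer(s, X), y)
        assert (model.predict(apply_standardizer(s, X)) == y).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigError):
            train_svm(rng.random((10, 3)), np.ones(10))


class TestMlp:
    def test_softmax_output_is_a_probability_simplex(self, rng):
        X, y = _blobs(rng, n_per_class=30)
        model = MLPFreshnessClassifier(epochs=5, random_state=0).fit(X, y)
        p = model.predict_proba(rng.random((7, X.shape[1])))
        assert p.shape == (7, 4)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_training_is_reproducible(self, rng):
        X, y = _blobs(rng, n_per_class=25)
        m1 = MLPFreshnessClassifier(epochs=10, random_state=4).fit(X, y)
        m2 = MLPFreshnessClassifier(epochs=10, random_state=4).fit(X, y)
        for w1, w2 in zip(m1.coefs_, m2.coefs_):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_learns_well_separated_blobs(self, rng):
        X, y = _blobs(rng)
        s = fit_standardizer(X)
        model = train_ann(apply_standardizer(s, X), y, seed=1, epochs=40)
        acc = (model.predict(apply_standardizer(s, X)) == y).mean()
        assert acc > 0.9

    def test_feature_width_mismatch_rejected(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        model = MLPFreshnessClassifier(epochs=2, random_state=0).fit(X, y)
        with pytest.raises(ConfigError, match="features"):
            model.predict(rng.random((3, X.shape[1] + 1)))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigError):
            MLPFreshnessClassifier(epochs=1).fit(rng.random((10, 4)), np.ones(10))


class TestCrossValidate:
    def test_single_point_grid_returns_that_point(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        res = cross_validate(X, y, "svm", grid=[{"C": 2.0}], folds=3, seed=0)
        assert res.best_params == {"C": 2.0}
        assert len(res.fold_scores[0]) == 3

    def test_fold_reduction_warning(self, rng):
        X = rng.random((12, 4))
        y = np.array([1] * 9 + [2] * 3)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = cross_validate(X, y, "svm", folds=5, seed=0)
        assert res.n_folds == 3

    def test_seeded_fold_assignment_reproducible(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        r1 = cross_validate(X, y, "svm", folds=4, seed=5)
        r2 = cross_validate(X, y, "svm", folds=4, seed=5)
        assert r1.fold_scores == r2.fold_scores


class _Oracle:
    """A 'model' that replays fixed predictions."""

    def __init__(self, pred):
        self.pred = np.asarray(pred)

    def predict(self, X):
        return self.pred


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 4, 2, 3])
        rep = evaluate(_Oracle(y), np.zeros((6, 2)), y)
        for level in (4, 3, 2):
            assert rep.overall_accuracy[level] == 100.0
            cm = rep.confusion(level)
            assert cm.sum() == 6
            assert np.trace(cm) == 6

    def test_three_of_four_correct(self):
        y = np.array([1, 2, 3, 4])
        pred = np.array([1, 2, 3, 1])
        rep = evaluate(_Oracle(pred), np.zeros((4, 2)), y)
        assert rep.overall_accuracy[4] == pytest.approx(75.0)

    def test_confusion_row_sums_equal_true_counts(self, rng):
        y = rng.integers(1, 5, size=50)
        pred = rng.integers(1, 5, size=50)
        rep = evaluate(_Oracle(pred), np.zeros((50, 2)), y)
        np.testing.assert_array_equal(
            rep.confusion4.sum(axis=1),
            [(y == k).sum() for k in (1, 2, 3, 4)])

    def test_coarsening_monotonicity_of_accuracy(self, rng):
        # merging classes preserves every correct match
        for _ in range(100):
            y = rng.integers(1, 5, size=30)
            pred = rng.integers(1, 5, size=30)
            rep = evaluate(_Oracle(pred), np.zeros((30, 2)), y)
            assert rep.overall_accuracy[2] >= rep.overall_accuracy[3] \
                >= rep.overall_accuracy[4]

    def test_empty_test_set_rejected(self):
        with pytest.raises(ConfigError):
            evaluate(_Oracle([]), np.zeros((0, 2)), np.array([]))


def test_coarsen_rejects_unknown_level():
    with pytest.raises(ConfigError):
        coarsen(np.array([1, 2]), 5)
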