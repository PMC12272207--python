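"""Connectome-based predictive modeling: selection, CV protocol, comparison."""

import numpy as np
import pytest

from enct import (
    compare_feature_sets,
    cross_validate,
    fit_cpm,
    select_features,
    summarize,
)
from enct.cpm import _fold_assignment


def planted_dataset(n=150, p=200, n_signal=10, r2=0.6, seed=0):
    """Features with a shared subject factor and a planted linear phenotype."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 1))
    X = 0.7 * g + rng.standard_normal((n, p))
    sig = rng.choice(p, n_signal, replace=False)
    signal = X[:, sig].sum(axis=1)
    noise_sd = np.sqrt(signal.var() * (1 - r2) / r2)
    y = signal + noise_sd * rng.standard_normal(n)
    return X, y, sig


class TestSelectFeatures:
    def test_strong_feature_selected_positive(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(100)
        X = rng.standard_normal((100, 20))
        X[:, 3] = y + 0.1 * rng.standard_normal(100)
        pos, neg = select_features(X, y)
        assert pos[3] and not neg[3]
        assert not (pos & neg).any()

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(50)
        X = np.ones((50, 5))
        pos, neg = select_features(X, y)
        assert not pos.any() and not neg.any()

    def test_null_selection_rate_matches_threshold(self):
        """Independent phenotype: expected selected fraction ~ p_threshold."""
        rng = np.random.default_rng(2)
        fractions = []
        for _ in range(50):
            X = rng.standard_normal((100, 200))
            y = rng.standard_normal(100)
            pos, neg = select_features(X, y, p_threshold=0.01)
            fractions.append((pos.sum() + neg.sum()) / 200)
        assert np.mean(fractions) == pytest.approx(0.01, abs=0.005)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="10 subjects"):
            select_features(np.zeros((5, 3)), np.zeros(5))

    def test_missing_values_rejected(self):
        X = np.zeros((12, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            select_features(X, np.zeros(12))


class TestSummarize:
    def test_single_positive_feature_is_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        pos = np.array([False, True, False])
        neg = np.zeros(3, dtype=bool)
        assert np.array_equal(summarize(X, (pos, neg)), X[:, 1])

    def test_equal_pos_neg_cancel(self):
        X = np.ones((5, 2))
        pos = np.array([True, False])
        neg = np.array([False, True])
        assert np.allclose(summarize(X, (pos, neg)), 0.0)

    def test_modes_match_manual_sums(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 5))
        pos = np.array([True, True, False, False, False])
        neg = np.array([False, False, True, False, False])
        s_pos = X[:, :2].sum(axis=1)
        s_neg = X[:, 2]
        assert np.allclose(summarize(X, (pos, neg), "positive"), s_pos)
        assert np.allclose(summarize(X, (pos, neg), "negative"), s_neg)
        assert np.allclose(summarize(X, (pos, neg), "difference"), s_pos - s_neg)

    def test_no_features_rejected(self):
        with pytest.raises(ValueError, match="no features"):
            summarize(np.zeros((4, 2)), (np.zeros(2, bool), np.zeros(2, bool)))


class TestCrossValidate:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 20))
        y = 3.0 * X[:, 7] + 1.0
        res = cross_validate(X, y, n_repeats=3, seed=0)
        assert np.all(res.performance > 0.99)

    def test_null_phenotype_mean_r_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 100))
        y = rng.standard_normal(200)
        res = cross_validate(X, y, n_repeats=25, seed=0)
        assert abs(res.performance.mean()) < 0.1

    def test_planted_signal_recovered(self):
        X, y, _ = planted_dataset()
        res = cross_validate(X, y, n_repeats=10, seed=0)
        assert np.median(res.performance) > 0.5

    def test_each_subject_predicted_once_per_repeat(self):
        X, y, _ = planted_dataset(n=60, p=50)
        res = cross_validate(X, y, n_repeats=2, k=10, seed=1)
        assert res.predictions.shape == (2, 60)
        for rep in range(2):
            assert np.array_equal(np.sort(np.unique(res.folds[rep])),
                                  np.arange(10))

    def test_seed_replay_is_bitwise_identical(self):
        X, y, _ = planted_dataset(n=80, p=60)
        a = cross_validate(X, y, n_repeats=3, seed=9)
        b = cross_validate(X, y, n_repeats=3, seed=9)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(a.folds, b.folds)

    def test_no_leakage_from_test_fold(self):
        """Permuting the held-out fold's phenotype values leaves that fold's
        predictions unchanged: selection and fitting see training data only."""
        X, y, _ = planted_dataset(n=100, p=80)
        fold = _fold_assignment(100, 10, seed=2, repeat=0)
        test0 = fold == 0
        y_perm = y.copy()
        rng = np.random.default_rng(0)
        y_perm[test0] = rng.permutation(y[test0])
        a = cross_validate(X, y, n_repeats=1, seed=2)
        b = cross_validate(X, y_perm, n_repeats=1, seed=2)
        assert np.allclose(a.predictions[0][test0], b.predictions[0][test0])

    def test_training_masks_ignore_test_data(self):
        X, y, _ = planted_dataset(n=100, p=80)
        train = np.arange(100) >= 10
        model_a = fit_cpm(X[train], y[train])
        y2 = y.copy()
        y2[:10] = 999.0  # corrupt test fold only
        model_b = fit_cpm(X[train], y2[train])
        assert np.array_equal(model_a.feature_mask_pos, model_b.feature_mask_pos)
        assert np.array_equal(model_a.feature_mask_neg, model_b.feature_mask_neg)


class TestCompareFeatureSets:
    def test_identical_results_give_half(self):
        X, y, _ = planted_dataset(n=60, p=40)
        a = cross_validate(X, y, n_repeats=5, seed=3)
        b = cross_validate(X, y, n_repeats=5, seed=3)
        assert compare_feature_sets(a, b) == pytest.approx(0.5)

    def test_strict_dominance_gives_zero(self):
        X, y, _ = planted_dataset(n=60, p=40)
        a = cross_validate(X, y, n_repeats=5, seed=3)
        b = cross_validate(X, y, n_repeats=5, seed=3)
        b.performance = a.performance - 0.2  # b strictly worse everywhere
        assert compare_feature_sets(a, b) == 0.0

    def test_matches_direct_count(self):
        X, y, _ = planted_dataset(n=60, p=40, seed=7)
        rng = np.random.default_rng(8)
        a = cross_validate(X, y, n_repeats=10, seed=3)
        b = cross_validate(X + 0.5 * rng.standard_normal(X.shape), y,
                           n_repeats=10, seed=3)
        expect = np.mean(a.performance < b.performance) + 0.5 * np.mean(
            a.performance == b.performance
        )
        assert compare_feature_sets(a, b) == pytest.approx(expect)

    def test_mismatched_splits_rejected(self):
        X, y, _ = planted_dataset(n=60, p=40)
        a = cross_validate(X, y, n_repeats=5, seed=3)
        b = cross_validate(X, y, n_repeats=5, seed=4)
        with pytest.raises(ValueError, match="identical fold splits"):
            compare_feature_sets(a, b)
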