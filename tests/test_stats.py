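"""Metrics, agreement coefficients, corrected t-test, stratified folds."""

import numpy as np
import pytest
from scipy import stats as sps

from koosgrade import (
    PairedDiffs,
    accuracy,
    confusion,
    corrected_ttest,
    cv_test_train_ratio,
    fleiss_kappa,
    ma_mae,
    stratified_kfold,
    weighted_f1,
    weighted_kappa_quadratic,
)
from koosgrade.errors import DegenerateInputError, ParameterError


class TestBasicMetrics:
    def test_accuracy_counts_matches(self):
        assert accuracy([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert accuracy([1, 2, 3, 4], [2, 3, 4, 1]) == 0.0
        assert accuracy([1, 2, 3, 4], [1, 2, 3, 1]) == 0.75

    def test_ma_mae_hand_example(self):
        # classes present: {1 (2 cases, errors 0,1), 2 (1 case, error 0)}
        assert ma_mae([1, 1, 2], [1, 2, 2]) == pytest.approx(0.25)

    def test_ma_mae_degenerate_cases(self):
        assert ma_mae([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0
        assert ma_mae([1, 2, 3, 4], [2, 3, 4, 3]) == 1.0  # every error is 1 grade

    def test_weighted_f1_binary_toy(self):
        # positive class: TP=1 FP=1 FN=1 -> F1 = 0.5; negative symmetric
        assert weighted_f1([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_f1_matches_sklearn(self, seed):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(seed)
        yt = rng.integers(1, 5, size=60)
        yp = rng.integers(1, 5, size=60)
        assert weighted_f1(yt, yp) == pytest.approx(
            f1_score(yt, yp, average="weighted", zero_division=0), abs=1e-12
        )

    def test_empty_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            accuracy([], [])


class TestConfusion:
    def test_diagonal_for_perfect_predictions(self):
        cm = confusion([1, 2, 3, 4], [1, 2, 3, 4])
        assert np.trace(cm.counts) == 4 and cm.counts.sum() == 4

    def test_row_sums_are_supports(self):
        yt = [1, 1, 2, 3, 3, 3, 4]
        cm = confusion(yt, [1, 2, 2, 3, 4, 3, 4])
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [2, 1, 3, 1])

    def test_accuracy_recomputed_from_trace(self):
        rng = np.random.default_rng(1)
        yt = rng.integers(1, 5, size=50)
        yp = rng.integers(1, 5, size=50)
        assert confusion(yt, yp).accuracy() == pytest.approx(accuracy(yt, yp), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            confusion([1, 5], [1, 1])


class TestFleissKappa:
    def test_perfect_agreement(self):
        ratings = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [2, 2]])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_hand_computed_toy_table(self):
        # 6 cases, 2 raters; agreements on 4 cases.
        ratings = np.array([[1, 1], [1, 2], [2, 2], [3, 3], [3, 4], [4, 4]])
        # pooled proportions p = (3, 3, 3, 3)/12; P_e = 4*(1/4)^2 = 0.25
        # P_i = 1 for agreeing cases, 0 otherwise -> P_bar = 4/6
        expected = (4 / 6 - 0.25) / (1 - 0.25)
        assert fleiss_kappa(ratings) == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(2)
        ratings = rng.integers(1, 5, size=(40, 3))
        table, _ = aggregate_raters(ratings)
        assert fleiss_kappa(ratings) == pytest.approx(sm_fleiss(table), abs=1e-12)

    def test_single_category_rejected(self):
        with pytest.raises(DegenerateInputError):
            fleiss_kappa(np.ones((5, 3), dtype=int))

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(3)
        ratings = rng.integers(1, 5, size=(5000, 2))
        assert abs(fleiss_kappa(ratings)) < 0.05


class TestWeightedKappa:
    def test_identical_ratings(self):
        r = [1, 2, 3, 4, 2, 3]
        assert weighted_kappa_quadratic(r, r) == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # only grades 1 and 2 used; penalty (i-j)^2/9 -> 1/9 off-diagonal
        r1 = [1, 1, 2, 2]
        r2 = [1, 2, 2, 2]
        # obs disagreement = (1/4)*(1/9); marginals (0.5,0.5) vs (0.25,0.75)
        # exp disagreement = (0.5*0.75 + 0.5*0.25)*(1/9) = 0.5/9
        expected = 1 - (0.25 / 9) / (0.5 / 9)
        assert weighted_kappa_quadratic(r1, r2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_quadratic(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        r1 = rng.integers(1, 5, size=80)
        r2 = rng.integers(1, 5, size=80)
        assert weighted_kappa_quadratic(r1, r2) == pytest.approx(
            cohen_kappa_score(r1, r2, weights="quadratic"), abs=1e-12
        )

    def test_quadratic_penalty_scales_with_squared_distance(self):
        """A two-grade error (IV rated II) costs 4x a one-grade error
        (IV rated III) in the disagreement sum; a three-grade error 9x."""
        k = 4
        penalty = lambda i, j: (i - j) ** 2 / (k - 1) ** 2
        assert penalty(4, 2) / penalty(4, 3) == pytest.approx(4.0)
        assert penalty(4, 1) / penalty(4, 3) == pytest.approx(9.0)

    def test_zero_expected_disagreement_rejected(self):
        with pytest.raises(DegenerateInputError):
            weighted_kappa_quadratic([2, 2, 2], [2, 2, 2])


class TestCorrectedTTest:
    def test_zero_mean_difference(self):
        t, p = corrected_ttest(PairedDiffs([-0.1, 0.1, -0.2, 0.2], 0.25))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_identical_methods_give_t_zero(self):
        t, p = corrected_ttest(PairedDiffs([0.0] * 5, 0.25))
        assert (t, p) == (0.0, 1.0)

    def test_ratio_zero_reduces_to_classical_paired_t(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=8)
        b = a + rng.normal(scale=0.3, size=8)
        t, _ = corrected_ttest(PairedDiffs(a - b, 0.0))
        classical = sps.ttest_rel(a, b)
        assert t == pytest.approx(classical.statistic, abs=1e-10)

    def test_hand_arithmetic(self):
        diffs = np.array([0.02, 0.05, 0.01, 0.04, 0.03])
        ratio = 0.8 / 0.2
        dbar = diffs.mean()
        var = diffs.var(ddof=1)
        expected = dbar / np.sqrt((1 / 5 + 4.0) * var)
        t, _ = corrected_ttest(PairedDiffs(diffs, ratio))
        assert t == pytest.approx(expected, abs=1e-10)

    def test_correction_shrinks_the_statistic(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.05, 0.02, size=5)
        t_corr, _ = corrected_ttest(PairedDiffs(diffs, 0.25))
        t_classical, _ = corrected_ttest(PairedDiffs(diffs, 0.0))
        assert abs(t_corr) < abs(t_classical)

    def test_cv_ratio_conventions(self):
        assert cv_test_train_ratio(5) == pytest.approx(0.25)
        assert cv_test_train_ratio(5, paper_convention=True) == pytest.approx(4.0)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ParameterError):
            PairedDiffs([0.1], 0.25)


class TestStratifiedKFold:
    def test_308_cases_largest_fold_62(self):
        rng = np.random.default_rng(6)
        grades = np.concatenate([[1] * 15, [2] * 95, [3] * 100, [4] * 98])
        rng.shuffle(grades)
        folds = stratified_kfold(grades, k=5, seed=0)
        sizes = sorted(np.bincount(folds, minlength=5), reverse=True)
        assert sizes == [62, 62, 62, 61, 61]

    def test_exact_divisibility_balances_perfectly(self):
        grades = np.repeat([1, 2, 3, 4], 10)
        folds = stratified_kfold(grades, k=5, seed=1)
        for g in (1, 2, 3, 4):
            counts = np.bincount(folds[grades == g], minlength=5)
            assert (counts == 2).all()

    def test_seeded_determinism_and_variation(self):
        grades = np.repeat([1, 2, 3, 4], [7, 20, 23, 20])
        f1 = stratified_kfold(grades, k=5, seed=3)
        f2 = stratified_kfold(grades, k=5, seed=3)
        f3 = stratified_kfold(grades, k=5, seed=4)
        np.testing.assert_array_equal(f1, f2)
        assert not np.array_equal(f1, f3)
        for f in (f1, f3):
            for g in (1, 2, 3, 4):
                counts = np.bincount(f[grades == g], minlength=5)
                assert counts.max() - counts.min() <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            stratified_kfold([1, 2, 3], k=5)
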