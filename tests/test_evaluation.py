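"""ROC thresholding, confusion metrics, rank-sum test, bootstrap LOO."""

import numpy as np
import pytest
from scipy import stats

from slopact import (ConfusionCounts, MoodState, ParameterError,
                     classification_metrics, classify, confusion_counts,
                     evaluate_pair, gamma_grid_search, loo_bootstrap,
                     rank_sum_test, roc_curve, threshold_nearest_01)
from slopact.evaluation import ScoredSample
from oracles import ranksum_enumeration_oracle

DEP, MAN, REM = MoodState.DEP, MoodState.MAN, MoodState.REM


def _scored(pos, neg, pos_state=DEP, neg_state=MAN):
    return ([ScoredSample(f"p{i}", pos_state, float(v)) for i, v in enumerate(pos)]
            + [ScoredSample(f"n{i}", neg_state, float(v)) for i, v in enumerate(neg)])


class TestRocCurve:
    def test_separable_scores_reach_corner(self):
        curve = roc_curve(_scored([0.9, 0.8], [0.7, 0.1]), DEP)
        assert curve.auc == pytest.approx(1.0)
        assert len(curve.thresholds) == 5
        corner = np.flatnonzero((curve.fpr == 0) & (curve.tpr == 1))
        assert corner.size == 1

    def test_identical_distributions_on_diagonal(self):
        curve = roc_curve(_scored([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), DEP)
        assert curve.auc == pytest.approx(0.5)
        np.testing.assert_allclose(curve.tpr, curve.fpr)

    def test_endpoints_present_and_monotone(self, rng):
        curve = roc_curve(_scored(rng.normal(1, 1, 20), rng.normal(0, 1, 30)), DEP)
        assert curve.tpr[0] == curve.fpr[0] == 0.0
        assert curve.tpr[-1] == curve.fpr[-1] == 1.0
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_orientation_flips_for_low_scoring_positive_class(self):
        curve = roc_curve(_scored([0.1, 0.2], [0.8, 0.9]), DEP)
        assert curve.orientation == "low_score_positive"
        assert curve.auc == pytest.approx(1.0)

    def test_missing_class_raises(self):
        with pytest.raises(ParameterError):
            roc_curve([ScoredSample("a", DEP, 1.0)], DEP)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        pos = rng.normal(0.5, 1, 25)
        neg = rng.normal(0.0, 1, 35)
        curve = roc_curve(_scored(pos, neg), DEP)
        y = np.r_[np.ones(25), np.zeros(35)]
        s = np.r_[pos, neg]
        assert curve.auc == pytest.approx(max(roc_auc_score(y, s),
                                              1 - roc_auc_score(y, s)))


class TestThresholdNearest01:
    def test_separable_case_returns_lowest_positive_score(self):
        curve = roc_curve(_scored([0.9, 0.8], [0.7, 0.1]), DEP)
        assert threshold_nearest_01(curve) == pytest.approx(0.8)

    def test_perfect_separation_distance_zero(self):
        curve = roc_curve(_scored([5.0, 6.0, 7.0], [1.0, 2.0], DEP, MAN), DEP)
        thr = threshold_nearest_01(curve)
        counts = confusion_counts(_scored([5.0, 6.0, 7.0], [1.0, 2.0]),
                                  DEP, thr, curve.orientation)
        assert (counts.fp, counts.fn) == (0, 0)

    def test_diagonal_curve_picks_midpoint(self):
        curve = roc_curve(_scored([1.0, 2.0], [1.0, 2.0]), DEP)
        # on the diagonal the mid point (0.5, 0.5) is strictly nearest (0,1)
        assert threshold_nearest_01(curve) == pytest.approx(2.0)

    def test_distance_tie_picks_highest_tpr(self):
        curve = roc_curve(_scored([3.0, 1.0], [2.0, 0.0]), DEP)
        # (fpr,tpr) = (0, 0.5) and (0.5, 1) are equidistant from (0,1);
        # the tie rule prefers the higher-TPR point, threshold 1.0
        assert threshold_nearest_01(curve) == pytest.approx(1.0)


class TestClassificationMetrics:
    def test_balanced_75_percent_gives_mcc_half(self):
        se, sp, acc, mcc = classification_metrics(ConfusionCounts(3, 3, 1, 1))
        assert (acc, mcc) == (0.75, 0.5)

    def test_perfect_classifier_gives_mcc_one(self):
        assert classification_metrics(ConfusionCounts(5, 5, 0, 0))[3] == 1.0

    def test_total_inversion_gives_mcc_minus_one(self):
        assert classification_metrics(ConfusionCounts(0, 0, 5, 5))[3] == -1.0

    def test_degenerate_denominator_maps_to_zero(self):
        # classifier that calls everything positive
        assert classification_metrics(ConfusionCounts(5, 0, 5, 0))[3] == 0.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ParameterError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_antisymmetry_and_sklearn_parity(self, rng):
        from sklearn.metrics import matthews_corrcoef
        for _ in range(20):
            y = rng.integers(0, 2, 40)
            p = rng.integers(0, 2, 40)
            c = ConfusionCounts(tp=int(((y == 1) & (p == 1)).sum()),
                                tn=int(((y == 0) & (p == 0)).sum()),
                                fp=int(((y == 0) & (p == 1)).sum()),
                                fn=int(((y == 1) & (p == 0)).sum()))
            mcc = classification_metrics(c)[3]
            assert mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)
            flipped = ConfusionCounts(tp=c.fn, tn=c.fp, fp=c.tn, fn=c.tp)
            assert classification_metrics(flipped)[3] == pytest.approx(-mcc)
            # swapping which class is positive transposes the matrix
            swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
            assert classification_metrics(swapped)[3] == pytest.approx(mcc)


class TestRankSumTest:
    def test_disjoint_small_groups_exact_p(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_no_evidence(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) >= 0.99

    def test_exact_branch_matches_full_enumeration(self, rng):
        for _ in range(15):
            na, nb = rng.integers(2, 6), rng.integers(2, 6)
            a = np.round(rng.normal(size=na), 1)  # rounding induces ties
            b = np.round(rng.normal(size=nb), 1)
            assert rank_sum_test(a, b) == pytest.approx(
                ranksum_enumeration_oracle(list(a), list(b)), abs=1e-12)

    def test_exact_branch_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            expected = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="exact").pvalue
            assert rank_sum_test(a, b) == pytest.approx(expected, abs=1e-12)

    def test_large_planted_shift_is_significant(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 30)
            b = rng.normal(3, 1, 30)
            assert rank_sum_test(a, b) < 0.05

    def test_empty_group_raises(self):
        with pytest.raises(ParameterError):
            rank_sum_test([], [1.0])


class TestLooBootstrap:
    def test_separable_scores_classify_perfectly(self):
        samples = _scored([1.0, 1.0, 1.0, 1.0], [0.1, 0.2, 0.3, 0.4])
        mean, sd = loo_bootstrap(samples, (DEP, MAN), n_realisations=200, seed=0)
        assert (mean, sd) == (1.0, 0.0)

    def test_boundary_positive_can_fall_below_trained_threshold(self):
        # the trained threshold is the lowest positive training score, so a
        # held-out positive below every training positive is missed even on
        # separable data: mean accuracy is high but strictly below 1
        samples = _scored([1.0, 1.1, 1.2, 1.3], [0.1, 0.2, 0.3, 0.4])
        mean, _ = loo_bootstrap(samples, (DEP, MAN), n_realisations=400, seed=0)
        assert 0.8 <= mean < 1.0

    def test_deterministic_given_seed(self, rng):
        samples = _scored(rng.normal(0.5, 1, 15), rng.normal(0, 1, 15))
        r1 = loo_bootstrap(samples, (DEP, MAN), n_realisations=100, seed=7)
        r2 = loo_bootstrap(samples, (DEP, MAN), n_realisations=100, seed=7)
        assert r1 == r2

    def test_small_class_raises(self):
        samples = _scored([1.0], [0.1, 0.2])
        with pytest.raises(ParameterError):
            loo_bootstrap(samples, (DEP, MAN), n_realisations=10, seed=0)

    def test_loo_does_not_beat_resubstitution(self, rng):
        """Held-out accuracy stays within 3 SE of (and below) the
        full-data resubstitution accuracy on a planted-effect dataset."""
        samples = _scored(rng.normal(1.2, 1, 30), rng.normal(0, 1, 30))
        resub = evaluate_pair(samples, (DEP, MAN)).acc
        mean, sd = loo_bootstrap(samples, (DEP, MAN), n_realisations=1000, seed=1)
        assert mean <= resub + 3 * sd / np.sqrt(1000)


class TestEvaluatePair:
    def test_separable_data_perfect_metrics(self):
        res = evaluate_pair(_scored([2.0, 2.1, 2.2], [0.1, 0.2, 0.3]), (DEP, MAN))
        assert (res.se, res.sp, res.acc, res.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_counts_consistent_with_metrics(self, rng):
        res = evaluate_pair(_scored(rng.normal(0.8, 1, 20), rng.normal(0, 1, 25)),
                            (DEP, MAN))
        c = res.counts
        assert c.total == 45
        assert res.acc == pytest.approx((c.tp + c.tn) / c.total)


class TestGammaGridSearch:
    def test_coarse_grid_has_nine_rows(self, small_epochs):
        grid = np.round(np.arange(0.1, 0.91, 0.1), 2)
        table = gamma_grid_search(small_epochs, (DEP, MAN), m=6, delta=1e-3,
                                  grid=grid)
        assert len(table) == 9
        assert list(table["gamma"]) == sorted(table["gamma"])

    def test_fine_grid_has_sixteen_rows(self, small_epochs):
        grid = np.round(np.arange(0.80, 0.951, 0.01), 2)
        table = gamma_grid_search(small_epochs, (DEP, REM), m=6, delta=1e-3,
                                  grid=grid)
        assert len(table) == 16

    def test_gamma_below_delta_rejected(self, small_epochs):
        with pytest.raises(ParameterError):
            gamma_grid_search(small_epochs, (DEP, MAN), m=6, delta=1e-3,
                              grid=[0.0005])
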