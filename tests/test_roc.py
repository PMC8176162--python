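"""ROC construction, Hanley-McNeil inference, cutoffs and sample size."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from fluidresp import (
    auc_ci,
    compare_aucs,
    compare_aucs_permutation,
    empirical_roc,
    hanley_mcneil_se,
    paired_auc_correlation,
    predictive_values,
    sample_size_auc,
    youden_cutoff,
)
from fluidresp.roc import auc_p_vs_null, wald_ci_percent


class TestEmpiricalRoc:
    def test_hand_enumerated_auc(self):
        # responders {3,5}, non-responders {1,4}: 3 of 4 pairs concordant
        curve = empirical_roc([3, 5, 1, 4], [True, True, False, False])
        assert curve.auc == pytest.approx(0.75, abs=1e-12)

    def test_perfect_separation(self, separated_scores):
        scores, labels = separated_scores
        assert empirical_roc(scores, labels).auc == 1.0

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        a = empirical_roc(scores, labels).auc
        b = empirical_roc(scores, ~labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_roc([1.0, 2.0], [True, True])

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        curve = empirical_roc(rng.integers(0, 5, 40).astype(float), rng.random(40) < 0.5)
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)

    def test_trapezoid_equals_tie_corrected_u(self):
        # dual route: trapezoid AUC vs Mann-Whitney U (scipy) on tied data
        rng = np.random.default_rng(3)
        for _ in range(300):
            n_pos = int(rng.integers(2, 20))
            n_neg = int(rng.integers(2, 20))
            scores = rng.integers(0, 6, n_pos + n_neg).astype(float)
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            curve = empirical_roc(scores, labels)
            u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
            assert curve.auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        curve = empirical_roc(scores, labels)
        assert curve.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.45
        a = empirical_roc(scores, labels).auc
        b = empirical_roc(np.exp(scores / 2), labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestHanleyMcNeil:
    def test_worked_value_and_monte_carlo(self):
        se = hanley_mcneil_se(0.5, 18, 18)
        assert se == pytest.approx(0.0976, abs=5e-4)
        # Monte-Carlo SD of the empirical AUC under exchangeable scores
        rng = np.random.default_rng(6)
        labels = np.r_[np.ones(18, bool), np.zeros(18, bool)]
        aucs = [empirical_roc(rng.normal(size=36), labels).auc for _ in range(2000)]
        assert np.std(aucs) == pytest.approx(se, rel=0.1)

    def test_se_vanishes_near_perfect_auc(self):
        assert hanley_mcneil_se(0.999999, 18, 22) < 1e-3

    def test_doubling_group_sizes_shrinks_se_by_sqrt2(self):
        se1 = hanley_mcneil_se(0.85, 18, 22)
        se2 = hanley_mcneil_se(0.85, 36, 44)
        assert se1 / se2 == pytest.approx(math.sqrt(2), rel=0.05)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hanley_mcneil_se(1.0, 18, 22)

    def test_ci_degenerate_and_truncated(self):
        assert auc_ci(0.8, 0.0) == (0.8, 0.8)
        lo, hi = auc_ci(0.99, hanley_mcneil_se(0.99, 5, 5))
        assert hi == 1.0 and lo < 0.99

    def test_ci_width_matches_formula(self):
        se = hanley_mcneil_se(0.85, 18, 22)
        lo, hi = auc_ci(0.85, se)
        assert hi - lo == pytest.approx(2 * 1.959964 * se, rel=1e-4)

    def test_p_vs_null_significant_for_large_auc(self):
        curve = empirical_roc(
            np.r_[np.random.default_rng(7).normal(3, 1, 18), np.random.default_rng(8).normal(0, 1, 22)],
            np.r_[np.ones(18, bool), np.zeros(22, bool)],
        )
        assert auc_p_vs_null(curve) < 0.001


class TestCompareAucs:
    @staticmethod
    def _two_marker_cohort(seed=9, rho=0.6, n_pos=18, n_neg=22, mu=1.5):
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        xp = rng.standard_normal((n_pos, 2)) @ L.T + mu
        xn = rng.standard_normal((n_neg, 2)) @ L.T
        scores = np.vstack([xp, xn])
        labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
        return scores[:, 0], scores[:, 1], labels

    def test_self_comparison_is_null(self):
        a, _, labels = self._two_marker_cohort()
        curve = empirical_roc(a, labels)
        res = compare_aucs(curve, curve, paired=True, scores_a=a, scores_b=a, labels=labels)
        assert res.z_statistic == 0.0 and res.p_value == 1.0

    def test_unpaired_uses_zero_correlation(self):
        a, b, labels = self._two_marker_cohort()
        ca, cb = empirical_roc(a, labels), empirical_roc(b, labels)
        res = compare_aucs(ca, cb, paired=False)
        assert res.correlation_r == 0.0
        expected_z = (ca.auc - cb.auc) / math.sqrt(ca.se_auc**2 + cb.se_auc**2)
        assert res.z_statistic == pytest.approx(expected_z, abs=1e-12)

    def test_z_antisymmetric(self):
        a, b, labels = self._two_marker_cohort()
        ca, cb = empirical_roc(a, labels), empirical_roc(b, labels)
        r1 = compare_aucs(ca, cb, paired=True, scores_a=a, scores_b=b, labels=labels)
        r2 = compare_aucs(cb, ca, paired=True, scores_a=b, scores_b=a, labels=labels)
        assert r1.z_statistic == pytest.approx(-r2.z_statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_independent_curves_sign(self):
        rng = np.random.default_rng(10)
        labels = np.r_[np.ones(18, bool), np.zeros(22, bool)]
        strong = empirical_roc(np.r_[rng.normal(2, 1, 18), rng.normal(0, 1, 22)], labels)
        weak = empirical_roc(rng.normal(size=40), labels)
        res = compare_aucs(strong, weak, paired=False)
        assert res.z_statistic > 0
        assert res.p_value < 0.05

    def test_paired_requires_scores(self):
        a, b, labels = self._two_marker_cohort()
        ca, cb = empirical_roc(a, labels), empirical_roc(b, labels)
        with pytest.raises(ValueError, match="paired"):
            compare_aucs(ca, cb, paired=True)

    def test_correlation_model_against_monte_carlo(self):
        # quadrature r vs the sampling correlation of paired empirical AUCs
        rho, theta = 0.6, 0.85
        mu = math.sqrt(2) * stats.norm.ppf(theta)
        rng = np.random.default_rng(11)
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        a1, a2 = [], []
        for _ in range(1500):
            xp = rng.standard_normal((30, 2)) @ L.T + mu
            xn = rng.standard_normal((30, 2)) @ L.T
            s = np.vstack([xp, xn])
            a1.append(empirical_roc(s[:, 0], labels).auc)
            a2.append(empirical_roc(s[:, 1], labels).auc)
        assert paired_auc_correlation(rho, theta) == pytest.approx(
            np.corrcoef(a1, a2)[0, 1], abs=0.06
        )

    def test_permutation_cross_check_agrees_on_null(self):
        # identical-information markers: both methods should be non-significant
        a, b, labels = self._two_marker_cohort(seed=12, rho=0.9)
        ca, cb = empirical_roc(a, labels), empirical_roc(b, labels)
        hm_p = compare_aucs(ca, cb, paired=True, scores_a=a, scores_b=b, labels=labels).p_value
        perm_p = compare_aucs_permutation(a, b, labels, n_perm=400, seed=13)
        assert hm_p > 0.05 and perm_p > 0.05


class TestOperatingPoint:
    def test_tie_broken_toward_smallest_cutoff(self):
        op = youden_cutoff(empirical_roc([3, 5, 1, 4], [True, True, False, False]))
        assert op.cutoff == 1.0
        assert op.youden_j == pytest.approx(0.5)
        assert op.sensitivity == 100.0 and op.specificity == 50.0

    def test_perfect_separation_smallest_maximizer(self, separated_scores):
        scores, labels = separated_scores
        op = youden_cutoff(empirical_roc(scores, labels))
        assert op.youden_j == pytest.approx(1.0)
        assert op.cutoff == 0.0  # smallest cutoff achieving J = 1

    def test_wald_ci_truncation(self):
        lo, hi = wald_ci_percent(16 / 18, 18)
        assert hi == 100.0
        assert lo == pytest.approx(100 * (16 / 18 - 1.959964 * math.sqrt((16 / 18) * (2 / 18) / 18)), abs=0.01)

    def test_predictive_values_from_counts(self):
        # TP=15, FP=4, TN=18, FN=3
        pv = predictive_values(15 / 18, 18 / 22, 18, 22)
        assert pv["ppv"] == pytest.approx(100 * 15 / 19, abs=1e-9)
        assert pv["npv"] == pytest.approx(100 * 18 / 21, abs=1e-9)

    def test_perfect_specificity_gives_full_ppv(self):
        pv = predictive_values(0.5, 1.0, 18, 22)
        assert pv["ppv"] == 100.0

    def test_zero_denominator_reported_missing(self):
        pv = predictive_values(0.0, 1.0, 18, 22)  # nobody called positive
        assert pv["ppv"] is None and pv["ppv_ci"] is None
        assert pv["npv"] is not None


class TestSampleSize:
    def test_worked_value(self):
        res = sample_size_auc(0.8, 0.5, alpha=0.05, power=0.90, allocation=1.0, two_sided=True)
        assert res.n_pos == 17 and res.n_neg == 17 and res.total == 34

    def test_one_sided_is_smaller(self):
        two = sample_size_auc(0.8, two_sided=True).total
        one = sample_size_auc(0.8, two_sided=False).total
        assert one < two

    def test_monotone_in_effect_size(self):
        totals = [sample_size_auc(a).total for a in (0.7, 0.75, 0.8, 0.85, 0.9)]
        assert totals == sorted(totals, reverse=True)
        assert all(t1 >= t2 for t1, t2 in zip(totals, totals[1:]))

    def test_no_effect_raises(self):
        with pytest.raises(ValueError, match="no finite"):
            sample_size_auc(0.5, 0.5)
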