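"""Empirical ROC analysis with Hanley-McNeil inference.

The core object is the empirical ROC curve of a continuous predictor
against a binary responder label, with the positive-call convention
"score strictly greater than cutoff" (so a printed cutoff of ``> 0``
means any positive value calls a responder). The area under the curve is
computed by the trapezoid rule and is identical to the tie-corrected
Mann-Whitney statistic U/(n_pos*n_neg).

Standard errors, confidence intervals, the two-AUC z-test, and the
AUC-based sample-size search all use the Hanley-McNeil closed forms

    SE^2 = [th(1-th) + (n_pos-1)(Q1-th^2) + (n_neg-1)(Q2-th^2)] / (n_pos*n_neg)
    Q1 = th/(2-th),  Q2 = 2 th^2/(1+th)

For paired comparisons (two predictors on the same patients) the z
denominator subtracts 2*r*SE_a*SE_b, where r is the correlation between
the two empirical AUCs. r is obtained from the average of the within-class
rank correlations of the two predictors and the average AUC, mapped
through the bivariate binormal model (see :func:`paired_auc_correlation`).
A stratified permutation test is provided as a model-free cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "AucComparison",
    "SampleSizeResult",
    "empirical_roc",
    "hanley_mcneil_se",
    "auc_ci",
    "auc_p_vs_null",
    "youden_cutoff",
    "predictive_values",
    "wald_ci_percent",
    "paired_auc_correlation",
    "compare_aucs",
    "compare_aucs_permutation",
    "sample_size_auc",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with Hanley-McNeil AUC inference.

    ``thresholds[0]`` is ``-inf`` (call everything positive); the remaining
    thresholds are the distinct observed score values in increasing order.
    ``sensitivity[i]`` / ``specificity[i]`` are the fractions obtained when a
    patient is called positive iff score > ``thresholds[i]``.
    """

    predictor_name: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    se_auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class OperatingPoint:
    """Cutoff with its operating characteristics, on the percent scale.

    Sensitivity/specificity/predictive values are percentages with
    truncated Wald 95% CIs; ``youden_j`` is on the fraction scale.
    """

    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv_pred: float
    ppv_pred_ci: tuple[float, float]
    npv_pred: float
    npv_pred_ci: tuple[float, float]
    youden_j: float


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    correlation_r: float
    z_statistic: float
    p_value: float


@dataclass(frozen=True)
class SampleSizeResult:
    n_pos: int
    n_neg: int

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not (labels.any() and (~labels).any()):
        raise ValueError("both classes must be present to build a ROC curve")
    return scores, labels


def empirical_roc(scores, labels, predictor_name: str = "score") -> RocCurve:
    """Build the empirical ROC curve of ``scores`` for predicting ``labels``.

    Positive call when score > threshold. AUC is the trapezoid area over
    (1-specificity, sensitivity), equal to the tie-corrected Mann-Whitney
    U/(n_pos*n_neg); ties between a responder and a non-responder score
    contribute one half.
    """
    scores, labels = _check_binary(scores, labels)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    n_pos, n_neg = pos.size, neg.size
    thresholds = np.r_[-np.inf, np.unique(scores)]
    # P(pos > c) and P(neg <= c) via sorted-array bisection
    se = 1.0 - np.searchsorted(pos, thresholds, side="right") / n_pos
    sp = np.searchsorted(neg, thresholds, side="right") / n_neg
    fpr = 1.0 - sp
    # thresholds ascend => fpr descends from 1 to 0; integrate in ascending order
    auc = float(np.trapezoid(se[::-1], fpr[::-1]))
    if 0.0 < auc < 1.0:
        se_auc = hanley_mcneil_se(auc, n_pos, n_neg)
    else:
        se_auc = 0.0
    ci = auc_ci(auc, se_auc)
    return RocCurve(
        predictor_name=predictor_name,
        thresholds=thresholds,
        sensitivity=se,
        specificity=sp,
        auc=auc,
        se_auc=se_auc,
        ci95=ci,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must lie strictly between 0 and 1")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class sizes must be >= 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(var)


def auc_ci(auc: float, se_auc: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for the AUC, truncated to [0, 1]."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se_auc), min(1.0, auc + z * se_auc))


def auc_p_vs_null(curve: RocCurve, null: float = 0.5) -> float:
    """Two-sided p-value for AUC != null, using the HM SE at the null."""
    se0 = hanley_mcneil_se(null, curve.n_pos, curve.n_neg)
    z = (curve.auc - null) / se0
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ci_percent(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald CI for a proportion ``p`` (fraction), returned in percent, truncated to [0, 100]."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half)))


def _confusion_at(curve: RocCurve, i: int) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at threshold index ``i`` (call positive if score > threshold)."""
    tp = round(curve.sensitivity[i] * curve.n_pos)
    fn = curve.n_pos - tp
    tn = round(curve.specificity[i] * curve.n_neg)
    fp = curve.n_neg - tn
    return tp, fp, tn, fn


def predictive_values(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> dict[str, float | tuple[float, float] | None]:
    """PPV/NPV (percent, Wald CIs) at an operating point, sample prevalence.

    Returns ``None`` for a value whose denominator (number of positive or
    negative calls) is zero rather than coercing it to 0.
    """
    tp = round(sensitivity * n_pos)
    fn = n_pos - tp
    tn = round(specificity * n_neg)
    fp = n_neg - tn
    out: dict[str, float | tuple[float, float] | None] = {}
    if tp + fp > 0:
        ppv = tp / (tp + fp)
        out["ppv"] = 100.0 * ppv
        out["ppv_ci"] = wald_ci_percent(ppv, tp + fp)
    else:
        out["ppv"] = None
        out["ppv_ci"] = None
    if tn + fn > 0:
        npv = tn / (tn + fn)
        out["npv"] = 100.0 * npv
        out["npv_ci"] = wald_ci_percent(npv, tn + fn)
    else:
        out["npv"] = None
        out["npv_ci"] = None
    return out


def youden_cutoff(curve: RocCurve) -> OperatingPoint:
    """Operating point maximizing Youden's J = Se + Sp - 1; ties -> smallest cutoff.

    Only observed predictor values are candidate cutoffs: the -inf
    endpoint ("call everyone positive") is not a usable decision threshold,
    which matters in degenerate resamples where no cutoff achieves J > 0.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    i = 1 + int(np.argmax(j[1:]))  # argmax returns the first (smallest-threshold) maximizer
    tp, fp, tn, fn = _confusion_at(curve, i)
    sens = curve.sensitivity[i]
    spec = curve.specificity[i]
    pv = predictive_values(sens, spec, curve.n_pos, curve.n_neg)
    nan_ci = (math.nan, math.nan)
    return OperatingPoint(
        cutoff=float(curve.thresholds[i]),
        sensitivity=100.0 * sens,
        sensitivity_ci=wald_ci_percent(sens, curve.n_pos),
        specificity=100.0 * spec,
        specificity_ci=wald_ci_percent(spec, curve.n_neg),
        ppv_pred=math.nan if pv["ppv"] is None else pv["ppv"],
        ppv_pred_ci=nan_ci if pv["ppv_ci"] is None else pv["ppv_ci"],
        npv_pred=math.nan if pv["npv"] is None else pv["npv"],
        npv_pred_ci=nan_ci if pv["npv_ci"] is None else pv["npv_ci"],
        youden_j=float(j[i]),
    )


def paired_auc_correlation(rho_scores: float, theta: float, n_quad: int = 80) -> float:
    """Correlation between two empirical AUCs on the same patients.

    Under a bivariate binormal model in which the two markers have latent
    score correlation ``rho_scores`` in each class and common AUC ``theta``,
    the asymptotic correlation between the two empirical AUCs is

        r = Cov(Phi(X1), Phi(X2)) / Var(Phi(X))

    with (X1, X2) bivariate normal, unit variances, common mean
    mu = sqrt(2) * Phi^{-1}(theta) and correlation ``rho_scores`` (the
    positive- and negative-class projection terms are equal by symmetry, so
    the class sizes cancel). Evaluated by Gauss-Hermite quadrature; this is
    the population version of the published lookup-table for the paired
    AUC comparison.
    """
    if not -1.0 <= rho_scores <= 1.0:
        raise ValueError("rho_scores must be in [-1, 1]")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly between 0 and 1")
    if abs(rho_scores) == 1.0:
        return float(np.sign(rho_scores))
    mu = math.sqrt(2.0) * stats.norm.ppf(theta)
    nodes, weights = special.roots_hermitenorm(n_quad)
    w = weights / math.sqrt(2.0 * math.pi)
    phi1 = stats.norm.cdf(mu + nodes)
    # E[Phi(X1) Phi(X2)] with X2 | X1 decomposed on an independent node grid
    s = math.sqrt(1.0 - rho_scores**2)
    x2 = mu + rho_scores * nodes[:, None] + s * nodes[None, :]
    e12 = float(w @ (phi1 * (stats.norm.cdf(x2) @ w)))
    e1 = float(w @ phi1)  # equals theta up to quadrature error
    var = float(w @ phi1**2) - e1 * e1
    return (e12 - e1 * e1) / var


def _avg_rank_correlation(scores_a, scores_b, labels) -> float:
    """Average of the within-class Spearman correlations of two predictors."""
    labels = np.asarray(labels, dtype=bool)
    rs = []
    for mask in (labels, ~labels):
        r = stats.spearmanr(np.asarray(scores_a)[mask], np.asarray(scores_b)[mask]).statistic
        rs.append(0.0 if np.isnan(r) else float(r))
    return float(np.mean(rs))


def compare_aucs(
    curve_a: RocCurve,
    curve_b: RocCurve,
    paired: bool = False,
    scores_a=None,
    scores_b=None,
    labels=None,
) -> AucComparison:
    """Hanley-McNeil z-test for the difference of two AUCs.

    z = (auc_a - auc_b) / sqrt(SE_a^2 + SE_b^2 - 2 r SE_a SE_b); unpaired
    comparisons use r = 0. Paired comparisons require the per-patient score
    vectors (same patients, same labels): r is derived from the average
    within-class rank correlation and the average AUC via the binormal
    model, with Spearman converted to a latent Pearson correlation by
    rho = 2 sin(pi * r_s / 6).
    """
    if paired:
        if scores_a is None or scores_b is None or labels is None:
            raise ValueError("paired comparison requires scores_a, scores_b and labels")
        labels_arr = np.asarray(labels, dtype=bool)
        if labels_arr.sum() != curve_a.n_pos or labels_arr.sum() != curve_b.n_pos:
            raise ValueError("paired comparison requires both curves built on the same labels")
        r_s = _avg_rank_correlation(scores_a, scores_b, labels_arr)
        rho = 2.0 * math.sin(math.pi * r_s / 6.0)
        theta = (curve_a.auc + curve_b.auc) / 2.0
        theta = min(max(theta, 1e-9), 1.0 - 1e-9)
        r = paired_auc_correlation(rho, theta)
    else:
        r = 0.0
    var = curve_a.se_auc**2 + curve_b.se_auc**2 - 2.0 * r * curve_a.se_auc * curve_b.se_auc
    if var <= 0.0:
        z = 0.0 if curve_a.auc == curve_b.auc else math.inf * np.sign(curve_a.auc - curve_b.auc)
        p = 1.0 if curve_a.auc == curve_b.auc else 0.0
    else:
        z = (curve_a.auc - curve_b.auc) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(
        auc_a=curve_a.auc, auc_b=curve_b.auc, correlation_r=r, z_statistic=float(z), p_value=p
    )


def compare_aucs_permutation(scores_a, scores_b, labels, n_perm: int = 2000, seed=None) -> float:
    """Model-free paired comparison: per-patient marker-swap permutation p-value.

    Under the null of exchangeable markers, each patient's (a, b) pair is
    swapped with probability 1/2; the two-sided p-value is the add-one
    fraction of permuted |AUC_a - AUC_b| at least as large as observed.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    observed = abs(empirical_roc(scores_a, labels).auc - empirical_roc(scores_b, labels).auc)
    hits = 0
    for _ in range(n_perm):
        flip = rng.random(scores_a.size) < 0.5
        a = np.where(flip, scores_b, scores_a)
        b = np.where(flip, scores_a, scores_b)
        d = abs(empirical_roc(a, labels).auc - empirical_roc(b, labels).auc)
        if d >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def sample_size_auc(
    auc_alt: float,
    auc_null: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.90,
    allocation: float = 1.0,
    two_sided: bool = True,
    max_n_per_group: int = 100000,
) -> SampleSizeResult:
    """Smallest group sizes detecting ``auc_alt`` against ``auc_null``.

    Searches the smallest n_pos (with n_neg = ceil(allocation * n_pos))
    satisfying the Hanley-McNeil inequality

        |auc_alt - auc_null| >= z_{1-alpha(/2)} SE(auc_null) + z_{1-beta} SE(auc_alt)

    with both standard errors evaluated at the candidate group sizes.
    """
    if not 0.0 < auc_alt < 1.0 or not 0.0 < auc_null < 1.0:
        raise ValueError("AUCs must lie strictly between 0 and 1")
    delta = abs(auc_alt - auc_null)
    if delta == 0.0:
        raise ValueError("auc_alt equals auc_null: no finite sample size exists")
    if allocation <= 0.0:
        raise ValueError("allocation must be positive")
    z_a = stats.norm.ppf(1.0 - (alpha / 2.0 if two_sided else alpha))
    z_b = stats.norm.ppf(power)
    for n_pos in range(2, max_n_per_group + 1):
        n_neg = math.ceil(allocation * n_pos)
        se0 = hanley_mcneil_se(auc_null, n_pos, n_neg)
        se1 = hanley_mcneil_se(auc_alt, n_pos, n_neg)
        if delta >= z_a * se0 + z_b * se1:
            return SampleSizeResult(n_pos=n_pos, n_neg=n_neg)
    raise ValueError("no sample size found below max_n_per_group")
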