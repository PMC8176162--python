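"""Between- and within-group comparison layer (summary-table statistics).

These are entirely standard tests (scipy-backed); what this module owns is
the selection logic and the table-shaped reporting:

* between groups, continuous: Shapiro-Wilk normality screen at alpha=0.05
  in each group selects Student's t (both normal-compatible) vs
  Mann-Whitney U;
* between groups, categorical: chi-square without continuity correction,
  auto-substituted by Fisher's exact test when any expected cell count is
  below 5 (2x2 only);
* within group, pre/post: paired t on the differences when they pass the
  normality screen, else Wilcoxon signed-rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "compare_between_groups",
    "compare_within_group",
    "between_group_table",
    "within_group_table",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    comparison: str  # e.g. "responder vs nonresponder" or "T1 vs T2 (responder)"
    test_used: str  # students_t | mann_whitney | chi_square | fisher_exact | paired_t | wilcoxon_signed_rank
    statistic: float
    p_value: float
    summaries: dict


def _is_normalish(x: np.ndarray) -> bool:
    """Shapiro-Wilk screen; tiny or constant samples fall back to nonparametric."""
    if x.size < 3 or np.allclose(x, x[0]):
        return False
    return stats.shapiro(x).pvalue >= NORMALITY_ALPHA


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def compare_between_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    categorical: bool | None = None,
) -> ComparisonResult:
    """Responder-vs-non-responder comparison of one cohort variable.

    ``categorical=None`` infers: non-numeric or boolean columns are treated
    as categorical. Continuous p-values come from Student's t or
    Mann-Whitney per the normality screen; categorical from uncorrected
    chi-square, or Fisher's exact when any expected cell is below 5.
    """
    if variable not in cohort.columns:
        raise ValueError(f"variable {variable!r} not in cohort")
    col = cohort[variable]
    if col.isna().all():
        raise ValueError(f"variable {variable!r} is entirely missing")
    groups = [g for g in ("responder", "nonresponder") if (cohort[group_col] == g).any()]
    if len(groups) != 2:
        groups = sorted(cohort[group_col].dropna().unique())
        if len(groups) != 2:
            raise ValueError("between-group comparison needs exactly two groups")
    if categorical is None:
        categorical = col.dtype == bool or not pd.api.types.is_numeric_dtype(col)
    label = f"{groups[0]} vs {groups[1]}"
    if categorical:
        table = pd.crosstab(cohort[group_col], col).reindex(index=groups)
        expected = stats.contingency.expected_freq(table.to_numpy())
        if (expected < 5).any() and table.shape == (2, 2):
            odds, p = stats.fisher_exact(table.to_numpy())
            test, statistic = "fisher_exact", float(odds)
        else:
            res = stats.chi2_contingency(table.to_numpy(), correction=False)
            test, statistic, p = "chi_square", float(res.statistic), res.pvalue
        summaries = {g: table.loc[g].to_dict() for g in groups}
    else:
        a = cohort.loc[cohort[group_col] == groups[0], variable].dropna().to_numpy(dtype=float)
        b = cohort.loc[cohort[group_col] == groups[1], variable].dropna().to_numpy(dtype=float)
        if _is_normalish(a) and _is_normalish(b):
            res = stats.ttest_ind(a, b)
            test, statistic, p = "students_t", float(res.statistic), float(res.pvalue)
            summaries = {groups[0]: _mean_sd(a), groups[1]: _mean_sd(b)}
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)
            summaries = {groups[0]: _median_iqr(a), groups[1]: _median_iqr(b)}
    return ComparisonResult(
        variable=variable, comparison=label, test_used=test,
        statistic=statistic, p_value=float(p), summaries=summaries,
    )


def compare_within_group(
    cohort: pd.DataFrame,
    variable: str,
    t_before: str,
    t_after: str,
    group: str | None = None,
    group_col: str = "group",
) -> ComparisonResult:
    """Pre/post comparison of ``{variable}_{t_before}`` vs ``{variable}_{t_after}``.

    Paired t-test when the differences pass the normality screen, else
    Wilcoxon signed-rank. The reported change summary is exactly the
    (after - before) sample mean +/- SD.
    """
    cols = (f"{variable}_{t_before}", f"{variable}_{t_after}")
    for c in cols:
        if c not in cohort.columns:
            raise ValueError(f"cohort is missing column {c!r}")
    sub = cohort if group is None else cohort[cohort[group_col] == group]
    pair = sub[list(cols)].dropna()
    before = pair[cols[0]].to_numpy(dtype=float)
    after = pair[cols[1]].to_numpy(dtype=float)
    if before.size < 2:
        raise ValueError("need at least 2 paired observations")
    diff = after - before
    if np.allclose(diff, 0.0):
        test, statistic, p = "paired_t", 0.0, 1.0
    elif _is_normalish(diff):
        res = stats.ttest_rel(after, before)
        test, statistic, p = "paired_t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.wilcoxon(after, before)
        test, statistic, p = "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue)
    label = f"{t_before} vs {t_after}" + (f" ({group})" if group else "")
    summaries = {
        t_before: _mean_sd(before),
        t_after: _mean_sd(after),
        "change": _mean_sd(diff) if diff.size > 1 else f"{diff.mean():.1f}",
        "change_mean": float(diff.mean()),
        "change_sd": float(diff.std(ddof=1)),
    }
    return ComparisonResult(
        variable=variable, comparison=label, test_used=test,
        statistic=statistic, p_value=float(p), summaries=summaries,
    )


def between_group_table(cohort: pd.DataFrame, variables, group_col: str = "group") -> pd.DataFrame:
    """Demographic-table-shaped frame: one row per variable with summaries and p."""
    rows = []
    for v in variables:
        r = compare_between_groups(cohort, v, group_col=group_col)
        groups = r.comparison.split(" vs ")
        rows.append(
            {
                "variable": v,
                groups[0]: str(r.summaries[groups[0]]),
                groups[1]: str(r.summaries[groups[1]]),
                "test": r.test_used,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def within_group_table(
    cohort: pd.DataFrame, variables, t_before: str, t_after: str, group_col: str = "group"
) -> pd.DataFrame:
    """Challenge-table-shaped frame: per variable and group, pre/post/change and p."""
    rows = []
    for v in variables:
        for g in ("responder", "nonresponder"):
            if not (cohort[group_col] == g).any():
                continue
            r = compare_within_group(cohort, v, t_before, t_after, group=g, group_col=group_col)
            rows.append(
                {
                    "variable": v,
                    "group": g,
                    t_before: r.summaries[t_before],
                    t_after: r.summaries[t_after],
                    "change": r.summaries["change"],
                    "test": r.test_used,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)
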