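"""Group-comparison decision flow and linear regression.

Small-sample two-group comparisons follow the screening pipeline typical of
preclinical work: optional outlier screening (the reproducible 1.5 x IQR
surrogate for graphical stem-and-leaf inspection; removal is opt-in and
logged), Shapiro-Wilk normality per group plus Levene's variance-homogeneity
test, then an independent two-sided t-test when both gates pass and a
Mann-Whitney U test otherwise.  Associations between continuous measures
(GCE vs myo-inositol) use ordinary least squares.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "screen_outliers",
    "compare_groups",
    "regress",
    "sqrt_transform",
]


@dataclass
class ComparisonResult:
    """Outcome of the gated two-group comparison."""

    test_used: str                     # "t_test" | "mann_whitney" | "degenerate"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    levene_p: float
    outliers_removed: tuple = ()
    group_summaries: tuple[dict, ...] = ()
    alpha: float = 0.05


@dataclass
class RegressionResult:
    """Ordinary-least-squares fit y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float                     # two-sided slope p-value
    n: int


def screen_outliers(values, ids=None) -> tuple[np.ndarray, tuple]:
    """Flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Groups of fewer than 3 observations pass through unscreened.  Returns
    ``(kept_values, removed_ids)`` where ids default to positional indices.
    """
    v = np.asarray(values, dtype=float)
    if ids is None:
        ids = tuple(range(v.size))
    ids = tuple(ids)
    if len(ids) != v.size:
        raise ValueError("ids must align with values")
    if v.size < 3:
        return v, ()
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    removed = tuple(i for i, k in zip(ids, keep) if not k)
    return v[keep], removed


def _summary(v: np.ndarray) -> dict:
    return {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size)}


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    remove_outliers: bool = False,
    ids_a=None,
    ids_b=None,
) -> ComparisonResult:
    """Two-sided comparison of independent groups with parametric gating.

    The t-test branch is taken only when both groups pass Shapiro-Wilk
    normality AND Levene's test (center='mean', mirroring SPSS) at ``alpha``;
    otherwise an exact/tie-corrected Mann-Whitney U is used.  All gate
    p-values are reported.  Outlier removal (1.5 x IQR per group) happens
    only when explicitly requested and the removed ids are returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    removed: tuple = ()
    if remove_outliers:
        a, rem_a = screen_outliers(a, ids_a)
        b, rem_b = screen_outliers(b, ids_b)
        removed = tuple(("a", i) for i in rem_a) + tuple(("b", i) for i in rem_b)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")

    summaries = (_summary(a), _summary(b))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # no within-group variation: no distributional test is defined
        return ComparisonResult(
            "degenerate",
            statistic=float("nan"),
            p_value=1.0 if a[0] == b[0] else 0.0,
            normality_p=(float("nan"), float("nan")),
            levene_p=float("nan"),
            outliers_removed=removed,
            group_summaries=summaries,
            alpha=alpha,
        )

    def _shapiro_p(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return 0.0  # a point mass is maximally non-normal
        return float(sps.shapiro(v).pvalue)

    sw = (_shapiro_p(a), _shapiro_p(b))
    lev = float(sps.levene(a, b, center="mean").pvalue)

    if sw[0] > alpha and sw[1] > alpha and lev > alpha:
        res = sps.ttest_ind(a, b, equal_var=True)
        used = "t_test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann_whitney"
    return ComparisonResult(
        used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=sw,
        levene_p=lev,
        outliers_removed=removed,
        group_summaries=summaries,
        alpha=alpha,
    )


def regress(x, y) -> RegressionResult:
    """OLS of y on x with intercept; R^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


def sqrt_transform(values) -> np.ndarray:
    """Square-root variance-stabilizing transform for non-negative data."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("square-root transform requires non-negative values")
    return np.sqrt(v)
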