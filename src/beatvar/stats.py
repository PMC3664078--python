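"""Two-group comparison and correlation layer for extrema metrics.

Summaries and tests follow common clinical-statistics practice: every
variable gets a normality verdict; normally distributed data are
summarised as mean (SD) and compared with an independent two-sample
t-test (Welch form by default), anything else as median (IQR) compared
with the two-sided Mann-Whitney U test. Correlations are two-tailed
Pearson for normal data and Spearman otherwise. Significance is judged
at alpha = 0.05 and no multiple-testing correction is applied by
default (an optional Bonferroni/Benjamini-Hochberg adjustment is
available for the report layer).

The Mann-Whitney p-value is computed by full enumeration of the
``C(n1 + n2, n1)`` group assignments when the combined sample size is at
most :data:`EXACT_MW_LIMIT` (handling ties exactly), and by the normal
approximation with tie correction otherwise; at the sample sizes extrema
analyses produce (thousands of pairs) the approximation is the
appropriate regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "CorrelationResult",
    "summarize",
    "compare_groups",
    "correlate",
    "mannwhitney_exact",
    "is_normal",
]

ALPHA = 0.05

#: Largest combined sample size for which the Mann-Whitney null
#: distribution is enumerated exactly.
EXACT_MW_LIMIT = 10

#: Shapiro-Wilk is the default normality test up to this sample size;
#: beyond it the D'Agostino-Pearson omnibus test is used instead (the
#: Shapiro-Wilk p-value approximation degrades for very large samples).
SHAPIRO_MAX_N = 5000

NormalityTest = Literal["auto", "shapiro", "dagostino"]


@dataclass(frozen=True)
class GroupSummary:
    """Location/spread summary of one sample plus its normality verdict."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normal: bool

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group comparison."""

    test_name: str          # "independent-t" or "mann-whitney"
    statistic: float
    p_value: float
    group_a: GroupSummary
    group_b: GroupSummary
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class CorrelationResult:
    """Outcome of a two-tailed correlation test."""

    method: str             # "pearson" or "spearman"
    r: float
    p_value: float


def normality_pvalue(values: np.ndarray, test: NormalityTest = "auto") -> float:
    """P-value of a normality test; ``auto`` picks Shapiro-Wilk for
    small-to-moderate n and D'Agostino-Pearson for very large n."""
    x = np.asarray(values, dtype=float)
    if test == "auto":
        test = "shapiro" if len(x) <= SHAPIRO_MAX_N else "dagostino"
    if test == "shapiro":
        return float(sps.shapiro(x).pvalue)
    if test == "dagostino":
        return float(sps.normaltest(x).pvalue)
    raise ValueError(f"unknown normality test {test!r}")


def is_normal(
    values: Sequence[float] | np.ndarray,
    alpha: float = ALPHA,
    test: NormalityTest = "auto",
) -> bool:
    """Normality verdict: the test fails to reject at ``alpha``.

    Requires n >= 3; smaller or zero-variance samples are treated as
    non-normal (the nonparametric route is always valid for them).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return normality_pvalue(x, test) >= alpha


def summarize(
    values: Sequence[float] | np.ndarray,
    alpha: float = ALPHA,
    normality_test: NormalityTest = "auto",
) -> GroupSummary:
    """Mean/SD and median/quartiles of a sample with a normality verdict.

    Quartiles use linear interpolation of order statistics; SD is the
    sample (n-1) standard deviation, 0 for a single observation.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(
        n=len(x),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        normal=is_normal(x, alpha=alpha, test=normality_test),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a: #(a > b) pairs + half the ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mannwhitney_exact(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Enumerates all ``C(n1 + n2, n1)`` assignments of the pooled values
    to the two groups; the two-sided p-value is twice the smaller of the
    two tail probabilities of the observed U, capped at 1 (the standard
    doubling convention, which remains well defined when ties make the
    permutation distribution of U asymmetric). Intended for small
    samples (the cost is the binomial coefficient).

    Returns
    -------
    (U, p) for group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)
    # U is a multiple of 0.5, so a tiny slack makes the tail comparisons
    # robust to round-off
    n_low = n_high = 0
    total = math.comb(n1 + n2, n1)
    for group_a_idx in combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(group_a_idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_obs + 1e-12:
            n_low += 1
        if u >= u_obs - 1e-12:
            n_high += 1
    p = 2.0 * min(n_low, n_high) / total
    return u_obs, min(p, 1.0)


def compare_groups(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    force_test: Literal["independent-t", "mann-whitney"] | None = None,
    alpha: float = ALPHA,
    equal_var: bool = False,
    normality_test: NormalityTest = "auto",
) -> ComparisonResult:
    """Compare two independent samples, picking the test by normality.

    The independent t-test (Welch form unless ``equal_var``) is used
    when both samples pass the normality test; otherwise the two-sided
    Mann-Whitney U (exact enumeration for combined n <= 10, normal
    approximation with tie correction above). ``force_test`` overrides
    the automatic choice.

    Raises
    ------
    ValueError
        If either sample has fewer than 2 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    sa = summarize(a, alpha=alpha, normality_test=normality_test)
    sb = summarize(b, alpha=alpha, normality_test=normality_test)

    test = force_test
    if test is None:
        test = "independent-t" if (sa.normal and sb.normal) else "mann-whitney"

    if test == "independent-t":
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "mann-whitney":
        if len(a) + len(b) <= EXACT_MW_LIMIT:
            stat, p = mannwhitney_exact(a, b)
        else:
            res = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")

    return ComparisonResult(
        test_name=test,
        statistic=stat,
        p_value=min(p, 1.0),
        group_a=sa,
        group_b=sb,
        alpha=alpha,
    )


def correlate(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    method: Literal["auto", "pearson", "spearman"] = "auto",
    alpha: float = ALPHA,
    normality_test: NormalityTest = "auto",
) -> CorrelationResult:
    """Two-tailed correlation between two paired samples.

    ``auto`` uses Pearson only when both variables pass the normality
    test, Spearman otherwise.

    Raises
    ------
    ValueError
        Length mismatch or fewer than 3 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if method == "auto":
        both_normal = is_normal(x, alpha, normality_test) and is_normal(
            y, alpha, normality_test
        )
        method = "pearson" if both_normal else "spearman"
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        method=method, r=float(res.statistic), p_value=float(res.pvalue)
    )


def adjust_pvalues(
    pvalues: Sequence[float], method: Literal["bonferroni", "fdr_bh"]
) -> np.ndarray:
    """Optional multiple-testing adjustment (off by default everywhere)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")
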