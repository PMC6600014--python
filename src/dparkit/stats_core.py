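"""Shared statistical primitives.

Thin, validated wrappers with uniform return types around the classical
tests the pipeline uses everywhere: Benjamini-Hochberg FDR, Fisher's exact
test on 2x2 tables, the Wilcoxon rank-sum test (exact for small untied
samples, normal approximation with continuity correction otherwise),
the two-sample Kolmogorov-Smirnov test, Pearson/Spearman correlation, and
the Fisher r-to-z comparison of two independent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atanh, sqrt

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "bh_fdr",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "ks_two_sample",
    "correlation",
    "compare_correlations",
]

#: combined-sample-size ceiling below which the rank-sum test is exact
EXACT_WILCOXON_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or association test."""

    statistic: float
    p_value: float
    method: str
    alternative: str = "two-sided"
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns adjusted values in the input order; each is >= the raw p and
    <= 1, and adjusted values are monotone in the raw ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test for a 2x2 contingency table.

    The two-sided p-value sums hypergeometric probabilities of all tables
    (conditional on the margins) no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(np.asarray(t, dtype=float), np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = np.round(t).astype(np.int64)
    res = stats.fisher_exact(t, alternative=alternative)
    # the conditioned statistic is the top-left cell count (always finite);
    # the sample odds ratio rides in estimate and may be infinite
    return TestResult(
        statistic=float(t[0, 0]),
        p_value=float(min(res.pvalue, 1.0)),
        method="fisher_exact",
        alternative=alternative,
        estimate=float(res.statistic),
    )


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation null when the combined sample size is at most
    ``EXACT_WILCOXON_N`` and there are no ties; otherwise the normal
    approximation with midranks for ties and an optional continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= EXACT_WILCOXON_N and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "wilcoxon_rank_sum_exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=continuity
        )
        method = "wilcoxon_rank_sum_normal"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="ks_two_sample",
    )


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a t-based p-value.

    Spearman is Pearson on midranks.  Constant input has no defined
    correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(res.statistic)
    return TestResult(
        statistic=r,
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        estimate=r,
    )


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Compare two independent correlation coefficients via Fisher's r-to-z.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the r-to-z transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (atanh(r1) - atanh(r2)) / sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), method="fisher_r_to_z")
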