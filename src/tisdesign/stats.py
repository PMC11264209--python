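"""Statistical procedures for variant comparison.

Replicate summaries are reported as mean +/- SEM.  Two-group comparisons
dispatch on pre-tests at alpha = 0.05: Shapiro-Wilk for normality of each
group and a two-sided F-test for equality of variance; normal equal-variance
data get a pooled t-test, anything else a Mann-Whitney U test.  Rate-constant
comparisons against a reference use a one-sided Mann-Whitney U test
(alternative: the variant is larger) with Benjamini-Hochberg selection across
variants controlling the FDR at alpha = 0.05.

The Mann-Whitney p-value is exact (full enumeration of rank assignments) for
small samples and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FDRReport",
    "sem",
    "mann_whitney_one_sided",
    "benjamini_hochberg",
    "two_group_gate",
]

ALPHA = 0.05
EXACT_MAX_TOTAL = 20   # exact enumeration feasible below this combined n
                       # (covers the 9-vs-9 replicate design)


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    alternative: str
    n: tuple[int, int]

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class FDRReport:
    p_values: np.ndarray          # as given
    alpha: float
    rejected: np.ndarray          # boolean mask aligned to p_values
    thresholds: np.ndarray        # per-hypothesis BH threshold k*alpha/m (sorted order)

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def sem(values) -> float:
    """Standard error of the mean, sample SD (n-1) over sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("SEM requires at least two values")
    return float(v.std(ddof=1) / np.sqrt(len(v)))


def mann_whitney_one_sided(x, y) -> TestResult:
    """One-sided Mann-Whitney U: alternative 'x stochastically larger than y'.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise (scipy's method='auto' convention at our size cutoff).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= EXACT_MAX_TOTAL and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="greater", method=method)
    return TestResult(test=f"mann-whitney ({method})",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), alternative="greater",
                      n=(len(x), len(y)))


def benjamini_hochberg(p_values, alpha: float = ALPHA) -> FDRReport:
    """BH step-up: reject the hypotheses with the m' smallest p-values where
    m' is the largest k with p_(k) <= k*alpha/m (boundary inclusive)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresholds
    rejected = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.where(passed)[0]))
        rejected[order[:k + 1]] = True
    return FDRReport(p_values=p, alpha=alpha, rejected=rejected,
                     thresholds=thresholds)


def two_group_gate(x, y, alpha: float = ALPHA) -> tuple[str, TestResult]:
    """Pre-test and dispatch a two-group comparison (two-sided).

    Shapiro-Wilk on each group (normality) and an F-test on the variance
    ratio (equality of variance), both at ``alpha``; normal equal-variance
    data go to the pooled t-test, everything else (including degenerate
    zero-variance groups) to Mann-Whitney.  Returns (path, result) where path
    is "t-test" or "mann-whitney".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("pre-tests need n >= 3 per group")
    degenerate = x.var(ddof=1) == 0 or y.var(ddof=1) == 0
    parametric = False
    if not degenerate:
        norm_ok = (sps.shapiro(x).pvalue > alpha
                   and sps.shapiro(y).pvalue > alpha)
        f_stat = x.var(ddof=1) / y.var(ddof=1)
        df1, df2 = len(x) - 1, len(y) - 1
        p_one = sps.f.sf(f_stat, df1, df2) if f_stat >= 1 else sps.f.cdf(f_stat, df1, df2)
        var_ok = min(1.0, 2.0 * p_one) > alpha
        parametric = norm_ok and var_ok
    if parametric:
        res = sps.ttest_ind(x, y, equal_var=True)
        return "t-test", TestResult(test="t-test", statistic=float(res.statistic),
                                    p_value=float(res.pvalue),
                                    alternative="two-sided", n=(len(x), len(y)))
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return "mann-whitney", TestResult(test="mann-whitney",
                                      statistic=float(u.statistic),
                                      p_value=float(u.pvalue),
                                      alternative="two-sided",
                                      n=(len(x), len(y)))
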