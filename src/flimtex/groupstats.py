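"""Nonparametric group comparisons for per-cell / per-patient feature tables.

Independent groups are compared with the Mann-Whitney U test, paired
samples with the Wilcoxon signed-rank test, and marginal normality is
screened with a one-sample Kolmogorov-Smirnov statistic against a normal
law with estimated mean/SD.  Because the normal parameters are estimated
from the same sample, the plain KS reference distribution is too
conservative; the Lilliefors-corrected p-value is the default, with the
uncorrected variant available for comparability with legacy software.

All tests are two-sided.  No multiple-testing correction is applied by
default; :func:`adjust_pvalues` offers Bonferroni and Benjamini-Hochberg
for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "ks_normality",
    "adjust_pvalues",
]

_EXACT_MW_MAX = 8  # exact U distribution when min(n1, n2) <= 8 and no ties
_EXACT_W_MAX = 12  # exact signed-rank distribution when n <= 12 and no ties


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _clean(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name}: empty sample")
    if np.isnan(v).any():
        raise ValueError(f"{name}: sample contains NaN")
    return v


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Uses the exact U null distribution for small samples without ties,
    otherwise the tie-corrected normal approximation (no continuity
    correction, so tied/untied branches agree in the limit).
    """
    a = _clean(a, "a")
    b = _clean(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = min(a.size, b.size) <= _EXACT_MW_MAX
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=a.size,
        n2=b.size,
        method=f"mann-whitney-{method}",
    )


def wilcoxon_signed_rank(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (Wilcoxon's convention);
    n1 reports the retained pair count.  Exact null distribution for
    n <= 12 without tied absolute differences, else normal approximation.
    """
    d = _clean(paired_diffs, "paired_diffs")
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    absd = np.abs(d)
    has_ties = np.unique(absd).size < absd.size
    method = "exact" if (d.size <= _EXACT_W_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=d.size,
        n2=0,
        method=f"wilcoxon-{method}",
    )


def ks_normality(x, method: str = "lilliefors") -> TestResult:
    """One-sample KS test of normality with estimated mean/SD.

    ``method="lilliefors"`` (default) corrects the p-value for parameter
    estimation; ``method="ks"`` returns the uncorrected KS p-value, which
    is anti-conservative in the sense of rejecting too rarely.
    """
    v = _clean(x, "x")
    if v.size < 5:
        raise ValueError("need at least 5 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    if method == "lilliefors":
        stat, p = _lilliefors(v, dist="norm", pvalmethod="table")
    elif method == "ks":
        stat, p = sps.kstest(v, "norm", args=(v.mean(), sd))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        statistic=float(stat),
        p_value=float(np.clip(p, 0.0, 1.0)),
        n1=v.size,
        n2=0,
        method=f"ks-{method}",
    )


def adjust_pvalues(p_values, method: str = "none") -> np.ndarray:
    """Optionally adjust a vector of p-values (none | bonferroni | fdr_bh)."""
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p
    if method in {"bonferroni", "fdr_bh"}:
        return multipletests(p, method=method)[1]
    raise ValueError(f"unknown adjustment {method!r}")
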