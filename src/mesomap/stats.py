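"""Shared statistical primitives: Welch t, Benjamini-Hochberg FDR, Cohen's d.

These are thin, explicitly-contracted wrappers around scipy/statsmodels used
throughout the pipeline so that every module applies the same conventions
(two-tailed p, unequal-variance t, step-up FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    """Two-sample test outcome.

    statistic : signed test statistic (group a minus group b).
    dof       : Welch-Satterthwaite degrees of freedom (fractional).
    p         : two-tailed p-value.
    n_a, n_b  : group sizes.
    """

    statistic: float
    dof: float
    p: float
    n_a: int
    n_b: int


def welch_t(a, b) -> TestResult:
    """Two-tailed t-test assuming unequal group variances.

    Degenerate case: if both groups have zero variance and equal means the
    statistic is 0 and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, a.size, b.size)
        return TestResult(np.inf if a.mean() > b.mean() else -np.inf,
                          float(a.size + b.size - 2), 0.0, a.size, b.size)
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    dof = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return TestResult(float(res.statistic), float(dof), float(res.pvalue),
                      a.size, b.size)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (flags, adjusted) where ``flags[i]`` marks rejection at level ``q``
    and ``adjusted`` are the monotone BH-adjusted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return flags, adj


def cohens_d(a, b) -> float:
    """Cohen's d with the two-group pooled SD (n-1 weights).

    Returns NaN when the pooled SD is zero (effect size undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires at least 2 samples per group")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
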