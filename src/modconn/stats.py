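"""Shared inference primitives.

Permutation tests on group mean differences, Benjamini-Hochberg FDR,
Pearson chi-square on 2x2 tables, pooled-variance t-tests from summary
statistics, trapezoidal AUC and percentile bootstrap confidence intervals.

Every routine that draws random numbers takes an explicit ``seed`` (or a
``numpy.random.Generator``) so that whole-pipeline runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "permutation_test",
    "fdr_bh",
    "chi_square_2x2",
    "t_test_from_summary",
    "trapezoid_auc",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group statistical test.

    ``statistic`` is the observed test statistic, ``p`` its p-value,
    ``n`` the degrees of freedom (parametric tests) or the number of
    permutations (resampling tests), ``tails`` one- or two-tailed, and
    ``method`` a short label identifying the procedure.
    """

    statistic: float
    p: float
    n: int
    tails: str
    method: str


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permutation_test(x, y, n_perm: int = 5000, tails: str = "two",
                     seed=0) -> TestResult:
    """Label-permutation test on the difference of group means.

    The observed statistic is ``mean(x) - mean(y)``. Group labels are
    permuted ``n_perm`` times; the p-value uses the +1 correction
    ``(1 + exceedances) / (1 + n_perm)`` so it can never be zero.
    ``tails='two'`` compares absolute differences, ``tails='greater'``
    tests mean(x) > mean(y), ``tails='less'`` the reverse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if tails not in ("two", "greater", "less"):
        raise ValueError(f"unknown tails: {tails!r}")
    rng = _as_rng(seed)
    pooled = np.concatenate([x, y])
    n1 = x.size
    observed = x.mean() - y.mean()
    # one shuffled copy per permutation, vectorized over permutations
    perm = np.empty(n_perm)
    for k in range(n_perm):
        rng.shuffle(pooled)
        perm[k] = pooled[:n1].mean() - pooled[n1:].mean()
    if tails == "two":
        exceed = np.sum(np.abs(perm) >= abs(observed))
    elif tails == "greater":
        exceed = np.sum(perm >= observed)
    else:
        exceed = np.sum(perm <= observed)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return TestResult(float(observed), float(p), n_perm, tails,
                      "permutation mean difference")


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) <= 0) or np.any(t.sum(axis=1) <= 0):
        raise ValueError("all row and column margins must be positive")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), int(dof), "two", "pearson chi-square")


def t_test_from_summary(m1: float, s1: float, n1: int,
                        m2: float, s2: float, n2: int) -> TestResult:
    """Two-sample pooled-variance t-test from group means, SDs and sizes."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      n1 + n2 - 2, "two", "pooled two-sample t")


def trapezoid_auc(xs, ys) -> float:
    """Composite trapezoid integral of ``ys`` over strictly increasing ``xs``."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2:
        raise ValueError("AUC needs at least two grid points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have the same length")
    return float(np.trapezoid(ys, xs))


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed=0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    rng = _as_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
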