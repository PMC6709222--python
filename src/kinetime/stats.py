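"""Nonparametric group comparisons with permutation confirmation.

Each test reports the classical statistic and asymptotic p-value (scipy)
together with a permutation p-value: exact enumeration of the permutation
space when it has at most 1e5 elements, otherwise Monte Carlo with the
add-one rule p = (1 + #as-or-more-extreme) / (1 + n_perm).  Two-sided
p-values use the deviation of the statistic from its null center.  Default
10,000 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney_u", "wilcoxon_signed_rank",
           "spearman_rho", "cohens_d"]

EXACT_LIMIT = 100_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_perm: float
    n_perm: int
    effect_size: float = np.nan
    ci: tuple = (np.nan, np.nan)
    exact: bool = False
    extra: dict = field(default_factory=dict)


def _two_sided_from_center(null_stats: np.ndarray, observed: float,
                           center: float, exact: bool) -> float:
    dev = np.abs(null_stats - center)
    obs_dev = abs(observed - center)
    count = int(np.sum(dev >= obs_dev - 1e-12))
    if exact:
        return count / len(null_stats)
    return (1 + count) / (1 + len(null_stats))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x (midrank ties)."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:len(x)].sum() - len(x) * (len(x) + 1) / 2)


def mann_whitney_u(x, y, n_perm: int = 10_000, seed: int = 0) -> TestResult:
    """Two-tailed Mann-Whitney U test with label-permutation confirmation.

    The asymptotic p uses the normal approximation with tie correction;
    p_perm enumerates all group labelings when C(n, n1) <= 1e5.  Cohen's d
    (pooled-SD) is attached as the effect size, and a percentile CI of the
    permutation null deviation of the group mean difference is reported.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=len(x) * len(y) / 2, p_value=1.0, p_perm=1.0,
                          n_perm=0, effect_size=0.0, exact=True)
    u_obs = _u_statistic(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    center = len(x) * len(y) / 2.0
    try:
        from math import comb
        space = comb(n, n1)
    except OverflowError:
        space = np.inf
    if space <= EXACT_LIMIT:
        null = np.array([_u_statistic(pooled[list(ix)],
                                      np.delete(pooled, list(ix)))
                         for ix in combinations(range(n), n1)])
        p_perm = _two_sided_from_center(null, u_obs, center, exact=True)
        n_used, exact = len(null), True
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = _u_statistic(perm[:n1], perm[n1:])
        p_perm = _two_sided_from_center(null, u_obs, center, exact=False)
        n_used, exact = n_perm, False
    return TestResult(statistic=u_obs, p_value=float(res.pvalue), p_perm=p_perm,
                      n_perm=n_used, effect_size=cohens_d(x, y), exact=exact)


def wilcoxon_signed_rank(x, y=None, n_perm: int = 10_000, seed: int = 0) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test with sign-flip permutation.

    ``y=None`` tests the sample against zero.  Zero differences are
    dropped (as in the classical test); all-zero differences give p = 1.
    Exact sign-flip enumeration when 2^n <= 1e5.
    """
    x = np.asarray(x, float)
    d = x if y is None else x - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, p_perm=1.0, n_perm=0,
                          effect_size=0.0, exact=True)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    center = n * (n + 1) / 4.0
    res = sps.wilcoxon(d, alternative="two-sided",
                       method="approx" if n > 25 else "auto")
    if 2 ** n <= EXACT_LIMIT:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
        null = np.where(signs, ranks, 0.0).sum(axis=1)
        p_perm = _two_sided_from_center(null, w_obs, center, exact=True)
        n_used, exact = 2 ** n, True
    else:
        rng = np.random.default_rng(seed)
        flips = rng.random((n_perm, n)) < 0.5
        null = np.where(flips, ranks, 0.0).sum(axis=1)
        p_perm = _two_sided_from_center(null, w_obs, center, exact=False)
        n_used, exact = n_perm, False
    dz = np.nan
    if d.std(ddof=1) > 0:
        dz = d.mean() / d.std(ddof=1)
    return TestResult(statistic=w_obs, p_value=float(res.pvalue), p_perm=p_perm,
                      n_perm=n_used, effect_size=float(dz), exact=exact)


def spearman_rho(x, y, n_perm: int = 10_000, seed: int = 0) -> TestResult:
    """Spearman rank correlation (midranks) with permutation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult(statistic=np.nan, p_value=np.nan, p_perm=np.nan,
                          n_perm=0, exact=True)
    rho, p_asym = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    from math import factorial
    if factorial(len(x)) <= EXACT_LIMIT:
        from itertools import permutations
        null = np.array([sps.spearmanr(x, np.asarray(p)).statistic
                         for p in permutations(y)])
        p_perm = _two_sided_from_center(null, rho, 0.0, exact=True)
        n_used, exact = len(null), True
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = sps.spearmanr(x, rng.permutation(y)).statistic
        p_perm = _two_sided_from_center(null, rho, 0.0, exact=False)
        n_used, exact = n_perm, False
    return TestResult(statistic=float(rho), p_value=float(p_asym), p_perm=p_perm,
                      n_perm=n_used, effect_size=float(rho), exact=exact)


def cohens_d(x, y, paired: bool = False) -> float:
    """Cohen's d: mean difference over pooled SD, or over the SD of paired
    differences.  Zero-variance data give signed infinity (flagged by value)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf
        return float(d.mean() / sd)
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        diff = x.mean() - y.mean()
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return float((x.mean() - y.mean()) / np.sqrt(s2))
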