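"""Evaluation statistics for brain-age models.

Implements the small set of statistics the evaluation protocol relies on:
mean absolute error between predicted brain age and chronological age,
Pearson/Spearman correlations, the Mann-Whitney U test with a rank-biserial
effect size, percentile bootstrap confidence intervals, Benjamini-Hochberg
FDR adjustment, and the one-sample t-test. Distributional machinery is
delegated to scipy/statsmodels; the conventions (min-U reporting, tie
handling, interval type) are fixed here so results are reproducible.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, DomainError, ShapeError

__all__ = [
    "mae",
    "correlation",
    "mann_whitney",
    "bootstrap_ci",
    "bh_fdr",
    "one_sample_t",
]

# Exact Spearman permutation p-values are enumerated only up to this sample
# size (8! = 40,320 permutations); beyond it the t approximation is used.
EXACT_SPEARMAN_MAX_N = 8


def _as_1d(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def mae(pred: Sequence[float], age: Sequence[float]) -> float:
    """Mean absolute error (1/N) * sum |pred_i - age_i| in years."""
    p = _as_1d(pred, "pred")
    a = _as_1d(age, "age")
    if p.size != a.size:
        raise ShapeError(f"length mismatch: {p.size} vs {a.size}")
    if p.size == 0:
        raise ShapeError("mae requires at least one pair")
    return float(np.mean(np.abs(p - a)))


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman is computed as the Pearson correlation of midranks. Its p-value
    is exact (full permutation enumeration) for tie-free samples of size
    <= EXACT_SPEARMAN_MAX_N, otherwise it uses the usual t approximation
    with n - 2 degrees of freedom.
    """
    xv = _as_1d(x, "x")
    yv = _as_1d(y, "y")
    if xv.size != yv.size:
        raise ShapeError(f"length mismatch: {xv.size} vs {yv.size}")
    n = xv.size
    if n < 3:
        raise DomainError("correlation requires n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("correlation undefined for constant input")

    if method == "pearson":
        r, p = sps.pearsonr(xv, yv)
        return float(r), float(p)
    if method != "spearman":
        raise DomainError(f"unknown correlation method: {method!r}")

    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = float(sps.pearsonr(rx, ry)[0])

    tie_free = np.unique(xv).size == n and np.unique(yv).size == n
    if tie_free and n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return rho, p


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! rank pairings."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    # Correlation is monotone in sum(rx * ry_perm) for fixed marginals.
    sums = ry[perms] @ rx
    mean_r = n * (n + 1) ** 2 / 4.0
    denom = np.sum(rx**2) - mean_r  # identical for both tie-free margins
    rhos = (sums - mean_r) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Mann-Whitney U test.

    Returns ``(U, p, rank_biserial)`` where U follows the min-U convention:
    with U1 = #{(i,j): x_i < y_j} + 0.5 * #ties, the reported statistic is
    min(U1, n1*n2 - U1). The p-value uses the normal approximation with tie
    correction (two-sided, continuity-corrected); the rank-biserial effect
    size is 1 - 2U/(n1*n2).
    """
    xv = _as_1d(x, "x")
    yv = _as_1d(y, "y")
    if xv.size == 0 or yv.size == 0:
        raise DomainError("mann_whitney requires both groups nonempty")
    n1, n2 = xv.size, yv.size
    # scipy's U counts pairs with x > y (plus half-ties)
    res = sps.mannwhitneyu(xv, yv, alternative="two-sided", method="asymptotic")
    u_greater = float(res.statistic)
    u_less = n1 * n2 - u_greater
    u = min(u_less, n1 * n2 - u_less)
    p = float(res.pvalue)
    if np.ptp(np.concatenate([xv, yv])) == 0:
        p = 1.0  # all observations tied; no evidence of a shift
    rank_biserial = 1.0 - 2.0 * u / (n1 * n2)
    return u, p, rank_biserial


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float],
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``statistic``.

    Resamples with replacement ``n_resamples`` times; deterministic for a
    fixed seed.
    """
    v = _as_1d(values, "values")
    if v.size < 2:
        raise DomainError("bootstrap_ci requires n >= 2")
    if n_resamples < 1:
        raise DomainError("n_resamples must be >= 1")
    if not 0.0 < level < 1.0:
        raise DomainError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_resamples, v.size))
    stats = np.array([statistic(v[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = _as_1d(p_values, "p_values")
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_sample_t(values: Sequence[float], mu0: float) -> tuple[float, float]:
    """One-sample two-sided t-test of the mean against ``mu0``."""
    v = _as_1d(values, "values")
    if v.size < 2:
        raise DomainError("one_sample_t requires n >= 2")
    if np.std(v, ddof=1) == 0:
        raise DegenerateInputError("zero sample standard deviation")
    t, p = sps.ttest_1samp(v, mu0)
    return float(t), float(p)
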