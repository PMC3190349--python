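"""Rank-correlation and distribution-free interval statistics.

This module collects the inferential machinery the pipeline relies on:

* Spearman rank correlation with Fisher-z (``atanh``) confidence
  intervals, the standard normal-theory interval for a correlation
  coefficient with variance ``1/(n - 3)`` on the z scale.
* Bonferroni adjustment of a family-wise alpha across a battery of
  correlations.
* A conservative distribution-free confidence interval for the median
  built from order statistics and the Binomial(n, 1/2) distribution —
  the natural choice when the sample is small and visibly skewed, as
  test–retest volume differences tend to be.
* A correlation battery runner that applies all of the above to named
  column pairs of a table, with pairwise deletion of missing values.

p-values for Spearman's rho use the exact permutation distribution for
very small samples (n <= 9) and the t approximation
``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom
otherwise; the method used is recorded on each result.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "MedianCi",
    "spearman",
    "spearman_p_value",
    "fisher_ci",
    "bonferroni_threshold",
    "median_ci",
    "median_ci_ranks",
    "correlation_battery",
]


class InsufficientDataError(ValueError):
    """Raised when a sample is too small for the requested interval."""


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant input)."""


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman correlation with its Fisher-z interval and test."""

    var_x: str
    var_y: str
    r: float
    n: int
    ci_lo: float
    ci_hi: float
    p_value: float
    p_method: str
    bonferroni_alpha: float
    significant: bool


@dataclass(frozen=True)
class MedianCi:
    """A median with a distribution-free confidence interval.

    ``achieved_coverage`` is the exact coverage probability of the
    order-statistic interval (at least ``level`` by construction).
    """

    median: float
    ci_lo: float
    ci_hi: float
    level: float
    method: str
    n: int
    achieved_coverage: float


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average-ranked data.

    Ties receive average ranks. Raises if either variable is constant
    (the correlation is then undefined) or if fewer than 3 pairs are
    supplied.
    """
    xa = _as_finite_array(x, "x")
    ya = _as_finite_array(y, "y")
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a constant variable"
        )
    r = sps.spearmanr(xa, ya).statistic
    return float(r)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = rx.size
    count = 0
    total = 0
    sy = ry.std()
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        r_perm = float(np.mean(rx * (ryp - ryp.mean()) / sy))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_p_value(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, str]:
    """Two-sided p-value for Spearman's rho.

    Exact permutation enumeration for n <= ``exact_max_n``; otherwise
    the t approximation on n - 2 degrees of freedom. Returns
    ``(p, method)``.
    """
    xa = _as_finite_array(x, "x")
    ya = _as_finite_array(y, "y")
    r = spearman(xa, ya)
    n = xa.size
    if n <= exact_max_n:
        return _exact_permutation_p(xa, ya, r), "exact_permutation"
    if abs(r) >= 1.0:
        return 0.0, "t_approximation"
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return float(min(p, 1.0)), "t_approximation"


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``z = atanh(r)`` is treated as normal with standard error
    ``1/sqrt(n - 3)``; the interval is back-transformed with ``tanh``.
    The exact normal quantile is used (1.959964... at level 0.95), not
    the rounded 1.96.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 4:
        raise ValueError("Fisher interval requires n >= 4")
    if abs(r) == 1.0:
        logger.warning("fisher_ci: |r| = 1 gives a degenerate interval")
        return (r, r)
    z = math.atanh(r)
    z_crit = sps.norm.ppf(0.5 + level / 2.0)
    half = z_crit / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def bonferroni_threshold(family_alpha: float = 0.05, m_tests: int = 1) -> float:
    """Per-test alpha after Bonferroni correction: ``family_alpha / m``."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / m_tests


def median_ci_ranks(n: int, level: float = 0.95) -> tuple[int, int, float]:
    """Conservative order-statistic ranks for a median CI.

    Returns 1-based ranks ``(lo, hi)`` such that
    ``P(x_(lo) <= median <= x_(hi)) >= level`` for any continuous
    distribution, together with the exact achieved coverage
    ``1 - 2 * BinomCDF(lo - 1; n, 1/2)``. ``lo`` is the largest rank
    keeping each tail at or below ``(1 - level)/2``.
    """
    if n < 1:
        raise InsufficientDataError("empty sample")
    alpha = 1.0 - level
    # largest k with P(X <= k - 1) <= alpha/2, X ~ Binomial(n, 1/2)
    cdf = sps.binom.cdf(np.arange(n + 1), n, 0.5)
    lo = int(np.searchsorted(cdf, alpha / 2.0, side="right"))  # = count of cdf <= a/2
    if lo < 1:
        raise InsufficientDataError(
            f"no distribution-free {level:.0%} median CI exists for n={n}; "
            f"need n >= 6 at the 95% level"
        )
    hi = n + 1 - lo
    coverage = float(1.0 - 2.0 * cdf[lo - 1])
    return lo, hi, coverage


def median_ci(values: Sequence[float], level: float = 0.95) -> MedianCi:
    """Distribution-free confidence interval for the median.

    Endpoints are the order statistics at the conservative
    Binomial(n, 1/2) ranks, so the interval's exact coverage is at
    least ``level`` for any continuous parent distribution.
    """
    arr = _as_finite_array(values, "values")
    n = arr.size
    lo, hi, coverage = median_ci_ranks(n, level)
    s = np.sort(arr)
    med = float(np.median(s))
    ci_lo = float(s[lo - 1])
    ci_hi = float(s[hi - 1])
    return MedianCi(
        median=med,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        level=level,
        method="median_order_statistic",
        n=n,
        achieved_coverage=coverage,
    )


def correlation_battery(
    table: pd.DataFrame,
    pair_list: Sequence[tuple[str, str]],
    family_alpha: float = 0.05,
    m: int | None = None,
    level: float = 0.95,
) -> list[CorrelationResult]:
    """Run a battery of Spearman correlations over named column pairs.

    Rows missing either member of a pair are dropped pairwise (not
    listwise), so each pair keeps its own n. Pairs with fewer than 4
    complete rows are skipped with a log entry. The Bonferroni divisor
    ``m`` defaults to the number of requested pairs.
    """
    if m is None:
        m = len(pair_list)
    alpha = bonferroni_threshold(family_alpha, m)
    results: list[CorrelationResult] = []
    for var_x, var_y in pair_list:
        for col in (var_x, var_y):
            if col not in table.columns:
                raise KeyError(f"column {col!r} not in table")
        sub = table[[var_x, var_y]].dropna()
        n = len(sub)
        if n < 4:
            logger.warning(
                "skipping pair (%s, %s): only %d complete rows", var_x, var_y, n
            )
            continue
        x = sub[var_x].to_numpy(float)
        y = sub[var_y].to_numpy(float)
        r = spearman(x, y)
        ci_lo, ci_hi = fisher_ci(r, n, level)
        p, method = spearman_p_value(x, y)
        results.append(
            CorrelationResult(
                var_x=var_x,
                var_y=var_y,
                r=r,
                n=n,
                ci_lo=ci_lo,
                ci_hi=ci_hi,
                p_value=p,
                p_method=method,
                bonferroni_alpha=alpha,
                significant=bool(p < alpha),
            )
        )
    return results
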