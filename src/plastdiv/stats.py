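"""Rank and resampling statistics used by the diversity pipeline.

The sampling unit throughout is the locus: group comparisons (LSC vs SSC vs
IR, exon vs intron vs IGS) take per-locus SNP/kb values.  The Kruskal-Wallis
H statistic is computed from mid-ranks with the standard tie correction
1 - sum(t^3 - t) / (N^3 - N); its null distribution is chi-squared with k-1
degrees of freedom, supplemented by an exact/permutation p-value for tiny
samples where the asymptotic approximation is poor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats as sps


@dataclass
class KruskalWallisResult:
    statistic: float
    df: int
    pvalue: float  # chi-squared upper tail
    pvalue_exact: Optional[float] = None  # permutation p, small samples only
    tie_correction: float = 1.0


def chi_squared_upper_tail(x: float, df: int) -> float:
    """P(X >= x) for X ~ chi-squared(df): regularized upper incomplete gamma."""
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _h_statistic(values: np.ndarray, sizes: Sequence[int]) -> tuple[float, float]:
    """Tie-corrected H for pooled values split into consecutive groups."""
    n = len(values)
    ranks = sps.rankdata(values)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0.0:
        return 0.0, 0.0  # all values identical
    return h / tie, tie


def kruskal_wallis(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    exact_limit: int = 10,
    max_permutations: int = 100_000,
    seed: int = 0,
) -> KruskalWallisResult:
    """Kruskal-Wallis rank test across two or more groups of values.

    For total sample size N <= ``exact_limit`` a permutation p-value is also
    computed, enumerating all distinct assignments when feasible and otherwise
    sampling ``max_permutations`` seeded permutations.  When every value is
    identical H is defined as 0 with p = 1 (the tie factor would vanish).
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(arrays) - 1

    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(0.0, df, 1.0, pvalue_exact=1.0, tie_correction=0.0)

    h, tie = _h_statistic(pooled, sizes)
    p = chi_squared_upper_tail(h, df)

    p_exact = None
    if n <= exact_limit:
        p_exact = _permutation_pvalue(pooled, sizes, h, max_permutations, seed)
    return KruskalWallisResult(h, df, p, p_exact, tie)


def _permutation_pvalue(
    pooled: np.ndarray,
    sizes: Sequence[int],
    h_obs: float,
    max_permutations: int,
    seed: int,
) -> float:
    n = pooled.size
    n_distinct = math.factorial(n)
    for sz in sizes:
        n_distinct //= math.factorial(sz)
    tol = 1e-9
    if n_distinct <= max_permutations:
        count = total = 0
        for assignment in _group_assignments(n, sizes):
            h, _ = _h_statistic(pooled[assignment], sizes)
            total += 1
            if h >= h_obs - tol:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    for _ in range(max_permutations):
        rng.shuffle(idx)
        h, _ = _h_statistic(pooled[idx], sizes)
        if h >= h_obs - tol:
            count += 1
    return (count + 1) / (max_permutations + 1)


def _group_assignments(n: int, sizes: Sequence[int]):
    """Yield index orderings realising every distinct split into groups."""

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        sz = sizes_left[0]
        for combo in itertools.combinations(remaining, sz):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield combo + tail

    for order in rec(tuple(range(n)), list(sizes)):
        yield np.array(order)


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean.

    Resamples the values with replacement ``n_boot`` times using a seeded
    generator and returns the central ``level`` percentile interval of the
    resampled means.  A single value yields a degenerate interval with a
    warning.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values")
    if n_boot < 1000:
        raise ValueError("use at least 1000 bootstrap replicates")
    if vals.size == 1:
        warnings.warn("single value: degenerate confidence interval", stacklevel=2)
        v = float(vals[0])
        return (v, v)
    rng = np.random.default_rng(seed)
    means = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
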