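"""Independent brute-force oracles used to check the fast implementations.

Each oracle is written directly from the mathematical definition and shares
no code with the library: DTW as a top-down recursion over warping paths
(plus a full path enumerator for tiny grids), sample entropy as a literal
double-loop template counter, and WMD as an exact integer-unit transport
search over the scaled polytope (whose vertices are integral).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def dtw_all_paths(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimum cumulative cost by explicit enumeration of every monotone
    warping path from (0, 0) to (Tx-1, Ty-1).  Exponential; tiny grids only.
    """
    X, Y = np.atleast_2d(X.T).T, np.atleast_2d(Y.T).T
    tx, ty = len(X), len(Y)
    cost = np.linalg.norm(X[:, None, :] - Y[None, :, :], axis=2)
    best = [math.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += cost[i, j]
        if i == tx - 1 and j == ty - 1:
            best[0] = min(best[0], acc)
            return
        if i + 1 < tx:
            walk(i + 1, j, acc)
        if j + 1 < ty:
            walk(i, j + 1, acc)
        if i + 1 < tx and j + 1 < ty:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def dtw_recursive(X: np.ndarray, Y: np.ndarray) -> float:
    """Top-down memoized recursion over the same path space (handles the
    up-to-12-frame random suite where full enumeration is infeasible)."""
    X, Y = np.atleast_2d(X.T).T, np.atleast_2d(Y.T).T
    cost = np.linalg.norm(X[:, None, :] - Y[None, :, :], axis=2)
    tx, ty = cost.shape

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return float(cost[0, 0])
        opts = []
        if i > 0:
            opts.append(rec(i - 1, j))
        if j > 0:
            opts.append(rec(i, j - 1))
        if i > 0 and j > 0:
            opts.append(rec(i - 1, j - 1))
        return float(cost[i, j]) + min(opts)

    return rec(tx - 1, ty - 1)


def sampen_naive(series, m: int = 2, r_factor: float = 0.25) -> float:
    """Literal double-loop sample entropy.

    Ordered pairs i != j, strict Chebyshev inequality < r with
    r = r_factor * population std; both template lengths use starting
    indices i in [0, T - m).  Zero-variance series -> 0.0; zero match
    count at either length, or T < m + 2 -> NaN.
    """
    x = [float(v) for v in series]
    n = len(x)
    if n < m + 2:
        return math.nan
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sd == 0.0:
        return 0.0
    r = r_factor * sd
    n_templ = n - m
    count_m = count_m1 = 0
    for i in range(n_templ):
        for j in range(n_templ):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                count_m += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < r:
                count_m1 += 1
    if count_m == 0 or count_m1 == 0:
        return math.nan
    return -math.log(count_m1 / count_m)


def wmd_integer_units(cost: np.ndarray) -> float:
    """Exact WMD with uniform marginals by integer-unit enumeration.

    Scaling the m x n transport problem by L = lcm(m, n) makes every
    marginal an integer, so some optimal plan is integral; the search
    assigns each row's L/m units to columns by enumerating all bounded
    compositions, memoizing on remaining column capacities.
    """
    m, n = cost.shape
    L = math.lcm(m, n)
    row_units = L // m
    col_cap = L // n

    @lru_cache(maxsize=None)
    def rec(i: int, remaining: tuple[int, ...]) -> float:
        if i == m:
            return 0.0 if all(r == 0 for r in remaining) else math.inf
        best = math.inf

        def fill(j: int, left: int, rem: list[int], acc: float) -> None:
            nonlocal best
            if j == n:
                if left == 0:
                    best = min(best, acc + rec(i + 1, tuple(rem)))
                return
            for q in range(min(left, rem[j]) + 1):
                rem[j] -= q
                fill(j + 1, left - q, rem, acc + q * cost[i, j])
                rem[j] += q

        fill(0, row_units, list(remaining), 0.0)
        return best

    return rec(0, tuple([col_cap] * n)) / L
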