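"""One-sided two-sample Kolmogorov-Smirnov test with an exact permutation null.

The peak caller tests whether the log2(IP/Input) values of the few probes
inside a sliding window are stochastically *greater* than the array-wide
background.  Windows hold only a handful of probes, where the asymptotic
Smirnov tail is unreliable, so for small windows the p-value is computed
exactly under the permutation null: all C(m+n, m) assignments of the pooled
values to "window" and "background" labels, p = P(D >= D_obs).

Direct enumeration is impossible at array scale (n is the whole array), so
the exact p is obtained by lattice-path counting in integer arithmetic:

* tie-free pools: a first-passage (barrier-crossing) decomposition costing
  O(m^2) big-int operations per test;
* pools with ties: a dynamic program over tie groups that checks the barrier
  only at distinct-value boundaries (the ECDF convention), costing O(N*m).

Both routes agree exactly with brute-force enumeration; the test suite
enforces this against an independent itertools oracle.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence, Tuple

import numpy as np

__all__ = ["ks_one_sided", "EXACT_MAX_MIN_SIZE", "P_FLOOR"]

#: exact permutation p is used whenever min(m, n) <= this; above it the
#: one-sided asymptotic tail exp(-2 D^2 mn/(m+n)) is accurate enough.
EXACT_MAX_MIN_SIZE = 8

#: p-values are clipped into (P_FLOOR, 1].
P_FLOOR = 1e-300


def _d_numerator(win_sorted: np.ndarray, bg_sorted: np.ndarray) -> int:
    """Integer numerator of D = max_x [ECDF_bg(x) - ECDF_win(x)] over m*n.

    Evaluated at every distinct pooled value; the maximum can only be
    attained just below a window value, at a window value, or at the last
    pooled value (where the difference is 0), so those candidates suffice.
    """
    m, n = len(win_sorted), len(bg_sorted)
    win_lt = np.searchsorted(win_sorted, win_sorted, side="left")
    win_le = np.searchsorted(win_sorted, win_sorted, side="right")
    bg_lt = np.searchsorted(bg_sorted, win_sorted, side="left")
    bg_le = np.searchsorted(bg_sorted, win_sorted, side="right")
    cand_below = bg_lt * m - win_lt * n
    cand_at = bg_le * m - win_le * n
    best = max(int(cand_below.max()), int(cand_at.max()))
    return max(best, 0)


def _exact_p_untied(m: int, n: int, d_num: int) -> float:
    """Exact P(D >= d_num/(m*n)) for a tie-free pool, by first passage.

    A label assignment is a monotone lattice path from (0, 0) to (N, m) in
    (items-seen, window-items-seen) coordinates; the statistic exceeds the
    threshold iff the path touches the barrier diff(i, w) = i*m - w*(m+n)
    >= d_num.  The barrier can only be first touched by a background step,
    and for each window-count level w there is a unique first-touch cell
    (i_w, w), so absorbed paths decompose over at most m+1 cells.  All
    counting is exact integer arithmetic.
    """
    if d_num <= 0:
        return 1.0
    N = m + n
    comb = math.comb
    touches: list[tuple[int, int, int]] = []  # (w, i_w, first-touch path count)
    total = 0
    for w in range(m + 1):
        i_w = -(-(d_num + w * N) // m)  # ceil((d_num + w*N)/m)
        if i_w > N or i_w - w > n or i_w - 1 < w:
            continue
        paths = comb(i_w - 1, w)
        for w2, i2, f2 in touches:
            if w2 <= w and i2 <= i_w - 1:
                paths -= f2 * comb(i_w - 1 - i2, w - w2)
        if paths > 0:
            touches.append((w, i_w, paths))
            total += paths * comb(N - i_w, m - w)
    return min(max(total / comb(N, m), P_FLOOR), 1.0)


def _exact_p_tied(groups: Tuple[int, ...], m: int, n: int, d_num: int) -> float:
    """Exact P(D >= d_num/(m*n)) for a pool with tie groups, by DP.

    ``groups`` are the multiplicities of the distinct pooled values in sorted
    order.  Within a tie group labels are exchangeable (binomial weights) and
    the barrier is checked only at group boundaries — the same right-
    continuous ECDF convention used to compute the observed statistic.
    """
    if d_num <= 0:
        return 1.0
    N = m + n
    comb = math.comb
    alive = [0] * (m + 1)
    alive[0] = 1
    absorbed = 0
    i = 0
    for g in groups:
        new = [0] * (m + 1)
        for w in range(m + 1):
            if alive[w] == 0:
                continue
            for j in range(0, min(g, m - w) + 1):
                new[w + j] += alive[w] * comb(g, j)
        i += g
        for w in range(m + 1):
            if new[w] and (i - w) * m - w * n >= d_num:
                absorbed += new[w] * comb(N - i, m - w)
                new[w] = 0
        alive = new
    return min(max(absorbed / comb(N, m), P_FLOOR), 1.0)


@lru_cache(maxsize=100_000)
def _exact_p_cached(groups: Tuple[int, ...] | None, m: int, n: int, d_num: int) -> float:
    if groups is None:
        return _exact_p_untied(m, n, d_num)
    return _exact_p_tied(groups, m, n, d_num)


def _asymptotic_p(d: float, m: int, n: int) -> float:
    p = math.exp(-2.0 * d * d * (m * n) / (m + n))
    return min(max(p, P_FLOOR), 1.0)


def ks_one_sided(
    window_values: Sequence[float], background_values: Sequence[float]
) -> Tuple[float, float]:
    """One-sided two-sample KS test: window stochastically greater than background.

    Parameters
    ----------
    window_values : sequence of float
        Probe log-ratios inside the window (m >= 1).
    background_values : sequence of float
        Reference log-ratios (n >= 2), e.g. all other probes on the array.

    Returns
    -------
    (d_statistic, p_value)
        ``d_statistic`` is max_x [ECDF_bg(x) - ECDF_win(x)] clipped to [0, 1];
        ``p_value`` is exact (permutation null) when ``min(m, n) <=``
        :data:`EXACT_MAX_MIN_SIZE`, else the one-sided asymptotic tail
        ``exp(-2 D^2 mn/(m+n))``, clipped into (1e-300, 1].
    """
    win = np.sort(np.asarray(window_values, dtype=float))
    bg = np.sort(np.asarray(background_values, dtype=float))
    m, n = len(win), len(bg)
    if m < 1:
        raise ValueError("window_values must be non-empty")
    if n < 2:
        raise ValueError("background_values must hold at least 2 values")
    if not (np.isfinite(win).all() and np.isfinite(bg).all()):
        raise ValueError("KS inputs must be finite")

    d_num = _d_numerator(win, bg)
    d = d_num / (m * n)

    if min(m, n) <= EXACT_MAX_MIN_SIZE:
        pooled = np.concatenate([win, bg])
        values, counts = np.unique(pooled, return_counts=True)
        if len(values) == len(pooled):
            p = _exact_p_cached(None, m, n, d_num)
        else:
            p = _exact_p_cached(tuple(int(c) for c in counts), m, n, d_num)
    else:
        p = _asymptotic_p(d, m, n)
    return d, p
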