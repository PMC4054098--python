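"""Numba kernels for the circular binary segmentation max-statistic and permutation test.

The two-sample pooled-t statistic for an arc against its complement satisfies

    t^2 = (n - 2) * B / (SS_tot - B),   B = n / (k (n - k)) * (S_arc - k * T / n)^2

where S_arc is the arc sum, T the total sum, k the arc length and SS_tot the total
sum of squares about the mean. SS_tot is invariant under permutation and t^2 is
monotone in B, so both the max search and the permutation comparison operate on B
alone, needing only partial sums. By arc/complement symmetry only arc lengths
k <= n/2 are scanned.

Candidate arcs are restricted so that every resulting piece has at least
``min_width`` probes: for each k the valid start offsets are i = 0, i = n - k, the
interior band [mw, n-k-mw] and the wrapped band [n-k+mw, n-mw].
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["max_b_with_cuts", "permutation_exceedances", "t_from_b"]


@njit(cache=True, fastmath=True)
def _max_b(x: np.ndarray, mw: int):  # pragma: no cover - exercised via wrappers
    n = x.size
    S = np.empty(2 * n + 1)
    S[0] = 0.0
    for i in range(2 * n):
        S[i + 1] = S[i] + x[i % n]
    T = S[n]
    best = -1.0
    bi = -1
    bk = -1
    kmax = n // 2
    for k in range(mw, kmax + 1):
        if n - k < mw:
            break
        ck = k * T / n
        w = n / (k * (n - k))
        # single-cut candidates: arc starts at 0 or ends at n
        d = S[k] - ck
        v = d * d * w
        if v > best:
            best, bi, bk = v, 0, k
        d = S[n] - S[n - k] - ck
        v = d * d * w
        if v > best:
            best, bi, bk = v, n - k, k
        for i in range(mw, n - k - mw + 1):
            d = S[i + k] - S[i] - ck
            v = d * d * w
            if v > best:
                best, bi, bk = v, i, k
        for i in range(n - k + mw, n - mw + 1):
            d = S[i + k] - S[i] - ck
            v = d * d * w
            if v > best:
                best, bi, bk = v, i, k
    return best, bi, bk


@njit(cache=True, fastmath=True)
def _max_b_only(x: np.ndarray, mw: int) -> float:  # pragma: no cover
    n = x.size
    S = np.empty(2 * n + 1)
    S[0] = 0.0
    for i in range(2 * n):
        S[i + 1] = S[i] + x[i % n]
    T = S[n]
    best = -1.0
    kmax = n // 2
    for k in range(mw, kmax + 1):
        if n - k < mw:
            break
        ck = k * T / n
        w = n / (k * (n - k))
        d = S[k] - ck
        hi = d * d
        d = S[n] - S[n - k] - ck
        if d * d > hi:
            hi = d * d
        for i in range(mw, n - k - mw + 1):
            d = S[i + k] - S[i] - ck
            if d * d > hi:
                hi = d * d
        for i in range(n - k + mw, n - mw + 1):
            d = S[i + k] - S[i] - ck
            if d * d > hi:
                hi = d * d
        v = hi * w
        if v > best:
            best = v
    return best


def max_b_with_cuts(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max between-group SS over valid circular arcs, plus the implied cut positions.

    Returns ``(b_max, cut1, cut2)`` with cuts as 0-based split offsets in (0, n);
    ``cut2 = -1`` for a single-cut (edge arc) split. ``b_max < 0`` means no valid
    candidate exists.
    """
    b, i, k = _max_b(np.ascontiguousarray(x, dtype=np.float64), min_width)
    if b < 0:
        return -1.0, -1, -1
    n = x.size
    j = i + k
    if i == 0:
        return b, k, -1
    if j == n:
        return b, i, -1
    if j < n:
        return b, i, j
    return b, j - n, i


def permutation_exceedances(
    x: np.ndarray, min_width: int, b_obs: float, n_perm: int, max_exceed: int, seed: int
) -> tuple[int, int]:
    """Count permuted maxima >= observed, stopping once the split decision is fixed.

    Stopping when the exceedance count passes ``max_exceed`` is exact: the final
    p-value could only grow, so the test is already non-significant.
    """
    return _perm_kernel(
        np.ascontiguousarray(x, dtype=np.float64),
        min_width,
        b_obs,
        n_perm,
        max_exceed,
        seed,
    )


@njit(cache=True, fastmath=True)
def _perm_kernel(x, mw, b_obs, n_perm, max_exceed, seed):  # pragma: no cover
    np.random.seed(seed)
    xp = x.copy()
    exceed = 0
    thresh = b_obs * (1.0 - 1e-12)
    for p in range(n_perm):
        np.random.shuffle(xp)
        b = _max_b_only(xp, mw)
        if b >= thresh:
            exceed += 1
            if exceed > max_exceed:
                return exceed, p + 1
    return exceed, n_perm


def t_from_b(b: float, ss_tot: float, n: int) -> float:
    """Convert a between-group SS into the pooled-t magnitude."""
    if n <= 2 or b <= 0:
        return 0.0
    resid = ss_tot - b
    if resid <= 1e-12 * max(ss_tot, 1.0):
        return np.inf
    return float(np.sqrt((n - 2) * b / resid))
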