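"""Fast tie-corrected Kendall tau-b via Knight's O(n log n) algorithm.

tau-b is invariant under strictly monotone transforms, so each column is
first reduced to dense integer ranks; a pair of rank vectors is then sorted
by the combined (x, y) key and the discordant count obtained by counting
strict inversions of y with a bottom-up mergesort.  With integer counts the
result is bit-identical to the direct concordance/discordance formula.

Compiled with numba when available; a numpy fallback (scipy.stats.kendalltau)
is used otherwise.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@njit(cache=False)
def _merge_count(ys: np.ndarray) -> np.int64:
    """Strict inversion count (ys[i] > ys[j] for i < j) by mergesort."""
    n = ys.shape[0]
    arr = ys.copy()
    tmp = np.empty(n, dtype=arr.dtype)
    inv = np.int64(0)
    width = 1
    while width < n:
        i = 0
        while i < n:
            mid = min(i + width, n)
            hi = min(i + 2 * width, n)
            a, b, k = i, mid, i
            while a < mid and b < hi:
                if arr[b] < arr[a]:
                    inv += mid - a
                    tmp[k] = arr[b]
                    b += 1
                else:
                    tmp[k] = arr[a]
                    a += 1
                k += 1
            while a < mid:
                tmp[k] = arr[a]
                a += 1
                k += 1
            while b < hi:
                tmp[k] = arr[b]
                b += 1
                k += 1
            for j in range(i, hi):
                arr[j] = tmp[j]
            i += 2 * width
        width *= 2
    return inv


@njit(cache=False)
def _tau_b_from_sorted(xs: np.ndarray, ys: np.ndarray) -> float:
    """tau-b from rank vectors already sorted by (x, y)."""
    n = xs.shape[0]
    # ties in x and joint ties
    n1 = np.int64(0)
    n3 = np.int64(0)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        g = np.int64(j - i)
        n1 += g * (g - 1) // 2
        k = i
        while k < j:
            m = k
            while m < j and ys[m] == ys[k]:
                m += 1
            gg = np.int64(m - k)
            n3 += gg * (gg - 1) // 2
            k = m
        i = j
    # ties in y
    ys_sorted = np.sort(ys)
    n2 = np.int64(0)
    i = 0
    while i < n:
        j = i
        while j < n and ys_sorted[j] == ys_sorted[i]:
            j += 1
        g = np.int64(j - i)
        n2 += g * (g - 1) // 2
        i = j
    swaps = _merge_count(ys)
    tot = np.int64(n) * np.int64(n - 1) // 2
    cd = tot - n1 - n2 + n3 - 2 * swaps   # concordant minus discordant
    denom = np.sqrt(float(tot - n1) * float(tot - n2))
    if denom == 0.0:
        return np.nan
    return cd / denom


def dense_ranks(x: np.ndarray) -> np.ndarray:
    """Dense integer ranks (ties share a rank), for tau computations."""
    _, inv = np.unique(np.asarray(x), return_inverse=True)
    return inv.astype(np.int64)


def tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation of two vectors."""
    xr, yr = dense_ranks(x), dense_ranks(y)
    return tau_b_ranked(xr, yr, len(xr))


@njit(cache=False)
def _tau_b_pair(xr: np.ndarray, yr: np.ndarray) -> float:
    n = xr.shape[0]
    # order by (x, y); equal keys are fully tied pairs, so stability is moot
    key = xr * np.int64(n + 1) + yr
    order = np.argsort(key)
    return _tau_b_from_sorted(xr[order], yr[order])


def tau_b_ranked(xr: np.ndarray, yr: np.ndarray, n: int) -> float:
    return float(_tau_b_pair(xr.astype(np.int64), yr.astype(np.int64)))


@njit(cache=False)
def _pair_tau_precomputed(ys: np.ndarray, starts: np.ndarray, n1: np.int64,
                          n2: np.int64) -> float:
    """tau-b given y-ranks already ordered by x, with x-tie-group starts.

    ``starts`` delimits runs of tied x (last entry = n); within each run the
    ys are sorted in place so the inversion count skips x-tied pairs, and
    joint ties are counted from the equal-y runs inside the groups.
    """
    n = ys.shape[0]
    n3 = np.int64(0)
    for g in range(starts.shape[0] - 1):
        a, b = starts[g], starts[g + 1]
        if b - a > 1:
            ys[a:b] = np.sort(ys[a:b])
            k = a
            while k < b:
                m = k
                while m < b and ys[m] == ys[k]:
                    m += 1
                gg = np.int64(m - k)
                n3 += gg * (gg - 1) // 2
                k = m
    swaps = _merge_count(ys)
    tot = np.int64(n) * np.int64(n - 1) // 2
    cd = tot - n1 - n2 + n3 - 2 * swaps
    denom = np.sqrt(float(tot - n1) * float(tot - n2))
    if denom == 0.0:
        return np.nan
    return cd / denom


@njit(cache=False)
def _pairwise(ranks: np.ndarray, orders: np.ndarray, starts_flat: np.ndarray,
              starts_off: np.ndarray, tie_pairs: np.ndarray) -> np.ndarray:
    p = ranks.shape[0]
    n = ranks.shape[1]
    S = np.eye(p)
    ys = np.empty(n, dtype=np.int64)
    for i in range(p):
        o = orders[i]
        starts = starts_flat[starts_off[i]:starts_off[i + 1]]
        for j in range(i + 1, p):
            for k in range(n):
                ys[k] = ranks[j, o[k]]
            t = _pair_tau_precomputed(ys, starts, tie_pairs[i], tie_pairs[j])
            S[i, j] = S[j, i] = abs(t)
    return S


def pairwise_abs_tau(X: np.ndarray) -> np.ndarray:
    """|tau-b| for every column pair of X (constant columns give NaN)."""
    n, p = X.shape
    ranks = np.empty((p, n), dtype=np.int64)
    orders = np.empty((p, n), dtype=np.int64)
    tie_pairs = np.empty(p, dtype=np.int64)
    starts_list = []
    for j in range(p):
        r = dense_ranks(X[:, j])
        ranks[j] = r
        o = np.argsort(r, kind="stable")
        orders[j] = o
        rs = r[o]
        boundaries = np.flatnonzero(np.diff(rs)) + 1
        starts = np.concatenate(([0], boundaries, [n])).astype(np.int64)
        starts_list.append(starts)
        sizes = np.diff(starts)
        tie_pairs[j] = int(np.sum(sizes * (sizes - 1) // 2))
    starts_off = np.zeros(p + 1, dtype=np.int64)
    for j in range(p):
        starts_off[j + 1] = starts_off[j] + len(starts_list[j])
    starts_flat = np.concatenate(starts_list).astype(np.int64)
    return _pairwise(ranks, orders, starts_flat, starts_off, tie_pairs)
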