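"""JIT-compiled inner loops for the expensive estimators.

Two hot spots live here: the O(m²) median-of-pairwise-slopes used by the
Theil–Sen association, and the grid dynamic program behind the maximal
information coefficient.  Both have pure-Python brute-force oracles in the
test suite; this module is purely a performance implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2 = float(np.log(2.0))


@njit(cache=True, nogil=True)
def _select_kth(a, k):
    """In-place quickselect: after return, a[k] holds the k-th smallest and
    a[:k] holds only elements ≤ a[k].  Median-of-three pivoting."""
    lo = 0
    hi = a.shape[0] - 1
    while True:
        if hi - lo < 3:
            for p in range(lo + 1, hi + 1):
                v = a[p]
                q = p - 1
                while q >= lo and a[q] > v:
                    a[q + 1] = a[q]
                    q -= 1
                a[q + 1] = v
            return a[k]
        mid = (lo + hi) // 2
        # order a[lo], a[mid], a[hi]
        if a[mid] < a[lo]:
            a[lo], a[mid] = a[mid], a[lo]
        if a[hi] < a[lo]:
            a[lo], a[hi] = a[hi], a[lo]
        if a[hi] < a[mid]:
            a[mid], a[hi] = a[hi], a[mid]
        pivot = a[mid]
        a[mid], a[hi - 1] = a[hi - 1], a[mid]
        i = lo
        j = hi - 1
        while True:
            i += 1
            while a[i] < pivot:
                i += 1
            j -= 1
            while a[j] > pivot:
                j -= 1
            if i >= j:
                break
            a[i], a[j] = a[j], a[i]
        a[i], a[hi - 1] = a[hi - 1], a[i]
        if i == k:
            return a[k]
        if k < i:
            hi = i - 1
        else:
            lo = i + 1


@njit(cache=True, nogil=True)
def _median_inplace(a):
    n = a.shape[0]
    if n == 1:
        return a[0]
    k2 = n // 2
    hi = _select_kth(a, k2)
    if n % 2 == 1:
        return hi
    lo = a[0]
    for t in range(1, k2):
        if a[t] > lo:
            lo = a[t]
    return 0.5 * (lo + hi)


@njit(cache=True, nogil=True)
def median_pairwise_slope(x, y):
    """Median of (y[j]-y[i])/(x[j]-x[i]) over all pairs with x[j] != x[i].

    Returns (slope, n_valid_pairs); slope is 0.0 when no pair has distinct
    x values (caller maps that to a zero association).
    """
    m = x.shape[0]
    nmax = m * (m - 1) // 2
    slopes = np.empty(nmax, dtype=np.float64)
    k = 0
    for i in range(m - 1):
        xi = x[i]
        yi = y[i]
        for j in range(i + 1, m):
            dx = x[j] - xi
            if dx != 0.0:
                slopes[k] = (y[j] - yi) / dx
                k += 1
    if k == 0:
        return 0.0, 0
    return _median_inplace(slopes[:k]), k


@njit(cache=True, nogil=True)
def _equipartition(sorted_vals, b):
    """Greedy near-equal partition of sorted values into ≤ b groups.

    Runs of equal values are never split.  Returns a group index per sorted
    position; the number of groups actually used may be smaller than ``b``
    under heavy ties.
    """
    m = sorted_vals.shape[0]
    assign = np.empty(m, dtype=np.int64)
    row = 0
    row_size = 0
    placed = 0
    desired = m / b
    i = 0
    while i < m:
        j = i + 1
        while j < m and sorted_vals[j] == sorted_vals[i]:
            j += 1
        run = j - i
        if row_size > 0 and row < b - 1 and abs(row_size + run - desired) >= abs(
            row_size - desired
        ):
            row += 1
            row_size = 0
            desired = (m - placed) / (b - row)
        for t in range(i, j):
            assign[t] = row
        row_size += run
        placed += run
        i = j
    return assign


@njit(cache=True, nogil=True)
def _max_char_one_orientation(x, y, B, c):
    """Best normalized grid information with y equipartitioned, x optimized.

    For each row count b (2 ≤ b ≤ B/2) the y axis is equipartitioned into
    ≤ b rows; the x axis is partitioned optimally (over clump/superclump
    boundaries) into l = 2..⌊B/b⌋ columns by dynamic programming.  Returns
    max over (l, b) of I / log2(min(l, rows_used)).
    """
    m = x.shape[0]
    best = 0.0
    max_b = int(B / 2.0)
    if max_b < 2:
        return 0.0
    order_x = np.argsort(x, kind="mergesort")
    order_y = np.argsort(y, kind="mergesort")
    y_sorted = y[order_y]
    # x-units: runs of equal x in x-order (points sharing an x value can
    # never be separated by a column boundary)
    unit_start = np.empty(m + 1, dtype=np.int64)
    n_units = 0
    i = 0
    while i < m:
        unit_start[n_units] = i
        n_units += 1
        j = i + 1
        while j < m and x[order_x[j]] == x[order_x[i]]:
            j += 1
        i = j
    unit_start[n_units] = m

    row_of = np.empty(m, dtype=np.int64)  # per original index
    for b in range(2, max_b + 1):
        a_max = int(B / b)
        if a_max < 2:
            break
        assign = _equipartition(y_sorted, b)
        rows_used = int(assign[m - 1]) + 1
        if rows_used < 2:
            continue
        for t in range(m):
            row_of[order_y[t]] = assign[t]
        row_marg = np.zeros(rows_used, dtype=np.int64)
        for t in range(m):
            row_marg[row_of[t]] += 1

        # clumps: maximal runs of consecutive x-units lying in a single row;
        # a unit spanning several rows ("mixed") is its own clump
        clump_end = np.empty(n_units, dtype=np.int64)  # point index past end
        n_clumps = 0
        prev_row = -2  # -2: nothing yet, -1: previous unit was mixed
        for u in range(n_units):
            s = unit_start[u]
            e = unit_start[u + 1]
            r = row_of[order_x[s]]
            for t in range(s + 1, e):
                if row_of[order_x[t]] != r:
                    r = -1
                    break
            if n_clumps > 0 and r >= 0 and r == prev_row:
                clump_end[n_clumps - 1] = e
            else:
                clump_end[n_clumps] = e
                n_clumps += 1
            prev_row = r

        # superclumps: cap DP size at k_hat boundaries, respecting clumps
        k_hat = max(1, int(c * a_max))
        if n_clumps > k_hat:
            merged = np.empty(k_hat, dtype=np.int64)
            n_super = 0
            size = 0
            placed = 0
            prev_end = 0
            desired = m / k_hat
            for q in range(n_clumps):
                run = clump_end[q] - prev_end
                prev_end = clump_end[q]
                if size > 0 and n_super < k_hat - 1 and abs(
                    size + run - desired
                ) >= abs(size - desired):
                    merged[n_super] = clump_end[q - 1]
                    n_super += 1
                    size = 0
                    desired = (m - placed) / (k_hat - n_super)
                size += run
                placed += run
            merged[n_super] = m
            n_super += 1
            bounds = merged[:n_super]
        else:
            bounds = clump_end[:n_clumps]
        k = bounds.shape[0]
        if k < 2:
            continue

        # cumulative per-row counts at superclump boundaries
        cum = np.zeros((k + 1, rows_used), dtype=np.int64)
        start = 0
        for t in range(k):
            for r in range(rows_used):
                cum[t + 1, r] = cum[t, r]
            for p in range(start, bounds[t]):
                cum[t + 1, row_of[order_x[p]]] += 1
            start = bounds[t]

        # column contribution to I(P;Q) in bits, for column = clumps (s, t]
        fm = float(m)
        term = np.full((k + 1, k + 1), -np.inf, dtype=np.float64)
        logm = np.log(fm)
        logrow = np.empty(rows_used, dtype=np.float64)
        for r in range(rows_used):
            logrow[r] = np.log(float(row_marg[r]))
        for s in range(k):
            for t in range(s + 1, k + 1):
                ncol = 0
                for r in range(rows_used):
                    ncol += cum[t, r] - cum[s, r]
                acc = 0.0
                lncol = np.log(float(ncol))
                for r in range(rows_used):
                    nrc = cum[t, r] - cum[s, r]
                    if nrc > 0:
                        acc += nrc * (np.log(float(nrc)) + logm - lncol - logrow[r])
                term[s, t] = acc / (fm * LOG2)

        # DP: best sum of column terms partitioning clumps 1..t into l columns
        a_eff = min(a_max, k)
        G = np.full((k + 1, a_eff + 1), -np.inf, dtype=np.float64)
        for t in range(1, k + 1):
            G[t, 1] = term[0, t]
        for l in range(2, a_eff + 1):
            for t in range(l, k + 1):
                bestv = -np.inf
                for s in range(l - 1, t):
                    v = G[s, l - 1] + term[s, t]
                    if v > bestv:
                        bestv = v
                G[t, l] = bestv
        for l in range(2, a_eff + 1):
            denom = np.log(float(min(l, rows_used))) / LOG2
            if denom > 0.0:
                val = G[k, l] / denom
                if val > best:
                    best = val
    return best


@njit(cache=True, nogil=True)
def mic_kernel(x, y, B, c):
    """MIC: max normalized characteristic value over both grid orientations."""
    v1 = _max_char_one_orientation(x, y, B, c)
    v2 = _max_char_one_orientation(y, x, B, c)
    v = v1 if v1 > v2 else v2
    if v < 0.0:
        v = 0.0
    if v > 1.0:
        v = 1.0
    return v
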