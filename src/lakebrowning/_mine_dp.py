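"""Numba kernels for the MINE characteristic-matrix computation.

The hot path of MIC/MAS is the ApproxMaxMI dynamic program: for a fixed
equipartition of one axis into q bins, find the partition of the other axis
into at most l columns (respecting "clumps") that maximizes mutual
information.  Everything here works on integer count arrays and a
precomputed ``plogp`` table, ``plogp[i] = (i/n) * log2(i/n)``, so the inner
loops are pure table arithmetic.

The DP is exact for the subproblem it solves: mutual information over all
points decomposes additively over columns as
``I = H(Q) + sum_cols [ -phi(n_col) + sum_rows phi(n_cell) ]`` with
``phi = plogp``, so a prefix recursion over clump boundaries finds the true
optimum (verified against exhaustive search in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def _build_clumps(row_sorted, new_flag, bounds):
    """Group points (sorted by the optimized axis) into clumps.

    A clump is a maximal run of consecutive points sharing a row label;
    points with identical axis values are forced into one group and, if that
    group spans several rows, it forms a clump of its own.  ``bounds``
    receives clump start indices; returns the clump count k (with
    ``bounds[k] = n`` as the terminal boundary).
    """
    n = row_sorted.shape[0]
    k = 0
    i = 0
    prev_label = -9999
    while i < n:
        j = i + 1
        label = row_sorted[i]
        mixed = False
        while j < n and new_flag[j] == 0:
            if row_sorted[j] != label:
                mixed = True
            j += 1
        lab = -2 if mixed else label
        if k == 0 or lab == -2 or prev_label == -2 or lab != prev_label:
            bounds[k] = i
            k += 1
        prev_label = lab
        i = j
    bounds[k] = n
    return k


@njit(cache=True)
def _superclumps(bounds, k, k_hat, out_bounds):
    """Merge clumps into ~k_hat superclumps of near-equal point mass."""
    n = bounds[k]
    j = 0
    h = 0
    rowsize = n / k_hat
    out_bounds[0] = 0
    j = 1
    h = 0.0
    for ci in range(k):
        start = bounds[ci]
        s = bounds[ci + 1] - start
        if h != 0.0 and j < k_hat and abs(h + s - rowsize) >= abs(h - rowsize):
            out_bounds[j] = start
            j += 1
            h = 0.0
            rowsize = (n - start) / (k_hat - (j - 1))
        h += s
    out_bounds[j] = n
    return j


@njit(cache=True)
def _dp_best(cum, cpts, q, max_l, plogp, hq):
    """Max mutual information per column budget l = 1..max_l.

    ``cum[t, r]`` is the number of points in rows r among the first t
    clumps, ``cpts[t]`` the total; the returned array is nondecreasing in l
    (a smaller budget's optimum is always attainable with a larger one).
    """
    k = cpts.shape[0] - 1
    g = np.empty((k + 1, k + 1))
    for s in range(k + 1):
        for t in range(s + 1, k + 1):
            v = -plogp[cpts[t] - cpts[s]]
            for r in range(q):
                v += plogp[cum[t, r] - cum[s, r]]
            g[s, t] = v
    best = np.full(max_l + 1, NEG)
    f = np.full(k + 1, NEG)
    for t in range(1, k + 1):
        f[t] = g[0, t]
    best[1] = f[k]
    top_l = max_l if max_l < k else k
    for l in range(2, top_l + 1):
        fn = np.full(k + 1, NEG)
        for t in range(l, k + 1):
            m = NEG
            for s in range(l - 1, t):
                v = f[s] + g[s, t]
                if v > m:
                    m = v
            fn[t] = m
        f = fn
        best[l] = f[k]
    out = np.empty(max_l + 1)
    run = NEG
    for l in range(1, max_l + 1):
        if best[l] > run:
            run = best[l]
        out[l] = run + hq
    out[0] = 0.0
    return out


@njit(cache=True)
def _axis_best_mi(row_sorted, new_flag, q, max_l, c, plogp):
    """Best MI (bits) for partitions of the sorted axis into <= l columns."""
    n = row_sorted.shape[0]
    bounds = np.empty(n + 1, np.int64)
    k = _build_clumps(row_sorted, new_flag, bounds)
    k_hat = c * max_l
    if k_hat < 2:
        k_hat = 2
    if k > k_hat:
        out_bounds = np.empty(k_hat + 1, np.int64)
        k = _superclumps(bounds, k, k_hat, out_bounds)
        bounds = out_bounds
    cum = np.zeros((k + 1, q), np.int64)
    cpts = np.zeros(k + 1, np.int64)
    for t in range(1, k + 1):
        for r in range(q):
            cum[t, r] = cum[t - 1, r]
        cpts[t] = bounds[t]
        for m in range(bounds[t - 1], bounds[t]):
            cum[t, row_sorted[m]] += 1
    hq = 0.0
    for r in range(q):
        hq -= plogp[cum[k, r]]
    return _dp_best(cum, cpts, q, max_l, plogp, hq)


@njit(cache=True)
def _char_entries(ymap, xmap, new_x, new_y, ybins, ybin_q, xbins, xbin_q,
                  b_budget, c, plogp, entries):
    """Fill the (cols, rows)-indexed characteristic entries (unnormalized).

    ``ymap[m]`` gives the original index of the point at x-rank m (so
    ``ybins[j, ymap[m]]`` is its y-row); ``xmap`` plays the mirror role for
    the y-sorted pass.  ``entries[a, b]`` collects the best raw MI for a
    grid with a columns and b rows; -1 marks grids outside the budget.
    """
    n = ymap.shape[0]
    entries[:, :] = -1.0
    row_sorted = np.empty(n, np.int64)
    for j in range(ybins.shape[0]):
        q = ybin_q[j]
        if q < 2:
            continue
        max_l = b_budget // q
        if max_l < 2:
            continue
        for m in range(n):
            row_sorted[m] = ybins[j, ymap[m]]
        res = _axis_best_mi(row_sorted, new_x, q, max_l, c, plogp)
        for l in range(2, max_l + 1):
            if res[l] > entries[l, q]:
                entries[l, q] = res[l]
    for j in range(xbins.shape[0]):
        q = xbin_q[j]
        if q < 2:
            continue
        max_l = b_budget // q
        if max_l < 2:
            continue
        for m in range(n):
            row_sorted[m] = xbins[j, xmap[m]]
        res = _axis_best_mi(row_sorted, new_y, q, max_l, c, plogp)
        for l in range(2, max_l + 1):
            if res[l] > entries[q, l]:
                entries[q, l] = res[l]


@njit(cache=True)
def _mic_from_entries(entries, log2min):
    mic = 0.0
    a_max = entries.shape[0]
    for a in range(2, a_max):
        for b in range(2, a_max):
            if entries[a, b] >= 0.0:
                v = entries[a, b] / log2min[a, b]
                if v > mic:
                    mic = v
    return mic


@njit(cache=True)
def _mas_from_entries(entries, log2min):
    mas = 0.0
    a_max = entries.shape[0]
    for a in range(2, a_max):
        for b in range(a + 1, a_max):
            if entries[a, b] >= 0.0 and entries[b, a] >= 0.0:
                v = abs(entries[a, b] - entries[b, a]) / log2min[a, b]
                if v > mas:
                    mas = v
    return mas
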