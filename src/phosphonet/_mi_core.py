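"""Numba kernels for adaptive-partition and hybrid-partition MI.

Everything here operates on integer rank vectors: 0 marks a missing entry,
observed entries of a vector carry ranks 1..n_obs (a permutation). MI is
returned in nats.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: chi-square split threshold (3 df, alpha = 0.05), the ARACNe-AP convention
CHI2_SPLIT = 7.815


@njit(cache=True)
def _partition(idx, px, py, lo, hi, xm, ym):
    """In-place partition of idx[lo:hi] into the four sub-cells of a split.

    Returns (b1, bx, b2): [lo,b1) x<xm,y<ym; [b1,bx) x<xm,y>=ym;
    [bx,b2) x>=xm,y<ym; [b2,hi) x>=xm,y>=ym.
    """
    i = lo
    j = hi - 1
    while i <= j:
        if px[idx[i]] < xm:
            i += 1
        else:
            t = idx[i]; idx[i] = idx[j]; idx[j] = t
            j -= 1
    bx = i
    i = lo; j = bx - 1
    while i <= j:
        if py[idx[i]] < ym:
            i += 1
        else:
            t = idx[i]; idx[i] = idx[j]; idx[j] = t
            j -= 1
    b1 = i
    i = bx; j = hi - 1
    while i <= j:
        if py[idx[i]] < ym:
            i += 1
        else:
            t = idx[i]; idx[i] = idx[j]; idx[j] = t
            j -= 1
    b2 = i
    return b1, bx, b2


@njit(cache=True)
def adaptive_mi(px, py, max_depth):
    """Adaptive-partition MI (nats) of complete unique rank vectors 1..m.

    Cells are recursively split at the midpoint of their rank bounds while a
    chi-square heterogeneity statistic over the four sub-cell counts exceeds
    CHI2_SPLIT; marginal cell probabilities are rank widths / m. With
    ``max_depth >= 0`` splitting is instead forced down to exactly that
    depth (a fixed 2^d x 2^d grid), which pins the final partition for
    oracle comparisons.
    """
    m = px.shape[0]
    if m < 2:
        return 0.0
    idx = np.arange(m)
    cap = 512
    st = np.empty((cap, 7), np.int64)
    st[0, 0] = 1; st[0, 1] = m + 1
    st[0, 2] = 1; st[0, 3] = m + 1
    st[0, 4] = 0; st[0, 5] = m
    st[0, 6] = 0
    top = 1
    mi = 0.0
    N = float(m)
    while top > 0:
        top -= 1
        x_lo = st[top, 0]; x_hi = st[top, 1]
        y_lo = st[top, 2]; y_hi = st[top, 3]
        lo = st[top, 4]; hi = st[top, 5]
        depth = st[top, 6]
        n = hi - lo
        if n == 0:
            continue
        wx = x_hi - x_lo
        wy = y_hi - y_lo
        do_split = False
        if wx >= 2 and wy >= 2:
            if max_depth >= 0:
                do_split = depth < max_depth
            elif n > 2:
                xm = x_lo + wx // 2
                ym = y_lo + wy // 2
                c00 = 0; c01 = 0; c10 = 0; c11 = 0
                for k in range(lo, hi):
                    a = px[idx[k]] >= xm
                    b = py[idx[k]] >= ym
                    if a:
                        if b:
                            c11 += 1
                        else:
                            c10 += 1
                    else:
                        if b:
                            c01 += 1
                        else:
                            c00 += 1
                e = n / 4.0
                chi2 = ((c00 - e) ** 2 + (c01 - e) ** 2
                        + (c10 - e) ** 2 + (c11 - e) ** 2) / e
                do_split = chi2 > CHI2_SPLIT
        if do_split:
            xm = x_lo + wx // 2
            ym = y_lo + wy // 2
            b1, bx, b2 = _partition(idx, px, py, lo, hi, xm, ym)
            st[top, 0] = x_lo; st[top, 1] = xm
            st[top, 2] = y_lo; st[top, 3] = ym
            st[top, 4] = lo; st[top, 5] = b1; st[top, 6] = depth + 1
            top += 1
            st[top, 0] = x_lo; st[top, 1] = xm
            st[top, 2] = ym; st[top, 3] = y_hi
            st[top, 4] = b1; st[top, 5] = bx; st[top, 6] = depth + 1
            top += 1
            st[top, 0] = xm; st[top, 1] = x_hi
            st[top, 2] = y_lo; st[top, 3] = ym
            st[top, 4] = bx; st[top, 5] = b2; st[top, 6] = depth + 1
            top += 1
            st[top, 0] = xm; st[top, 1] = x_hi
            st[top, 2] = ym; st[top, 3] = y_hi
            st[top, 4] = b2; st[top, 5] = hi; st[top, 6] = depth + 1
            top += 1
        else:
            mi += (n / N) * np.log(n * N / (wx * wy))
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def _rerank(v):
    """Re-rank unique positive integers to 1..len(v), order preserving."""
    m = v.shape[0]
    order = np.argsort(v)
    out = np.empty(m, np.int64)
    for t in range(m):
        out[order[t]] = t + 1
    return out


@njit(cache=True)
def hpmi_ranks(xr, yr, max_depth):
    """Hybrid-partition MI of two rank vectors with 0 = missing.

    Chain-rule combination: plug-in MI of the 2x2 observed/missing quadrant
    table plus (n11/n)-weighted adaptive-partition MI of the jointly
    observed points re-ranked among themselves. Returns
    (mi, n11, n00, n01, n10) with n01 = x-missing-only, n10 = y-missing-only.
    """
    n = xr.shape[0]
    n11 = 0; n00 = 0; n01 = 0; n10 = 0
    for i in range(n):
        xo = xr[i] > 0
        yo = yr[i] > 0
        if xo and yo:
            n11 += 1
        elif xo:
            n10 += 1
        elif yo:
            n01 += 1
        else:
            n00 += 1
    x_obs = n11 + n10
    x_mis = n01 + n00
    y_obs = n11 + n01
    y_mis = n10 + n00
    mi = 0.0
    fn = float(n)
    if n11 > 0:
        mi += (n11 / fn) * np.log(n11 * fn / (float(x_obs) * y_obs))
    if n10 > 0:
        mi += (n10 / fn) * np.log(n10 * fn / (float(x_obs) * y_mis))
    if n01 > 0:
        mi += (n01 / fn) * np.log(n01 * fn / (float(x_mis) * y_obs))
    if n00 > 0:
        mi += (n00 / fn) * np.log(n00 * fn / (float(x_mis) * y_mis))
    if n11 >= 4:
        jx = np.empty(n11, np.int64)
        jy = np.empty(n11, np.int64)
        k = 0
        for i in range(n):
            if xr[i] > 0 and yr[i] > 0:
                jx[k] = xr[i]
                jy[k] = yr[i]
                k += 1
        mi += (n11 / fn) * adaptive_mi(_rerank(jx), _rerank(jy), max_depth)
    if mi < 0.0:
        mi = 0.0
    return mi, n11, n00, n01, n10


@njit(cache=True)
def complete_case_mi(xr, yr):
    """Depleted-case MI: adaptive-partition MI over jointly observed points only."""
    n = xr.shape[0]
    n11 = 0
    for i in range(n):
        if xr[i] > 0 and yr[i] > 0:
            n11 += 1
    if n11 < 8:
        return 0.0
    jx = np.empty(n11, np.int64)
    jy = np.empty(n11, np.int64)
    k = 0
    for i in range(n):
        if xr[i] > 0 and yr[i] > 0:
            jx[k] = xr[i]
            jy[k] = yr[i]
            k += 1
    return adaptive_mi(_rerank(jx), _rerank(jy), -1)


@njit(cache=True)
def batch_mi(R, ia, ib, method, out):
    """MI for row pairs (ia[k], ib[k]) of rank matrix R. method 0 = hpMI, 1 = complete-case."""
    for k in range(ia.shape[0]):
        if method == 0:
            mi, _, _, _, _ = hpmi_ranks(R[ia[k]], R[ib[k]], -1)
            out[k] = mi
        else:
            out[k] = complete_case_mi(R[ia[k]], R[ib[k]])
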