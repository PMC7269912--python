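"""Brute-force reference for the dip statistic.

Independent of the fast implementation: for each candidate mode placement it
checks, by bisection on the sup-distance t, whether a unimodal distribution
function fits inside the tube [F - t, F + t], computing the greatest convex
minorant directly from its chord definition (O(m^3) per check).
"""

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def _hull_lower(xs, ys):
    m = len(xs)
    out = ys.astype(float).copy()
    for j in range(m):
        best = ys[j]
        for i in range(j + 1):
            for l in range(j, m):
                if i == l:
                    continue
                v = ys[i] + (ys[l] - ys[i]) * (xs[j] - xs[i]) / (xs[l] - xs[i])
                if v < best:
                    best = v
        out[j] = best
    return out


def _feasible(xs, bmin, bmax, n, s, mode_kind, k):
    up = bmin + s
    lo = bmax + 1.0 - s
    m = len(xs)
    if mode_kind == "at":
        li, ri = k, k
        left_lo = np.arange(m) < k
        right_lo = np.arange(m) > k
    else:
        li, ri = k, k + 1
        left_lo = np.arange(m) <= k
        right_lo = np.arange(m) >= k + 1
    hull = _hull_lower(xs[: li + 1], up[: li + 1])
    sel = left_lo[: li + 1]
    if np.any(hull[sel] < lo[: li + 1][sel] - 1e-12):
        return False
    # the concave side is the mirror image of the convex side
    rx = -xs[ri:][::-1]
    rup = (n - lo[ri:])[::-1]
    rlo = (n - up[ri:])[::-1]
    hull = _hull_lower(rx, rup)
    sel = right_lo[ri:][::-1]
    if np.any(hull[sel] < rlo[sel] - 1e-12):
        return False
    return True


def dip_reference(values, tol=1e-13):
    x = np.sort(np.asarray(values, float))
    n = len(x)
    xs, first = np.unique(x, return_index=True)
    m = len(xs)
    if m == 1:
        return 0.0
    counts = np.diff(np.append(first, n))
    bmin = first.astype(float)
    bmax = (first + counts - 1).astype(float)

    def any_feasible(s):
        for k in range(m):
            if _feasible(xs, bmin, bmax, n, s, "at", k):
                return True
        for k in range(m - 1):
            if _feasible(xs, bmin, bmax, n, s, "between", k):
                return True
        return False

    lo_s, hi_s = 0.0, float(n)
    while hi_s - lo_s > tol * n:
        mid = 0.5 * (lo_s + hi_s)
        if any_feasible(mid):
            hi_s = mid
        else:
            lo_s = mid
    return hi_s / n


def _lower_hull_vals(xs, ys):
    """Lower convex hull of (xs, ys) evaluated at every xs, via qhull."""
    m = len(xs)
    if m <= 2:
        return ys.astype(float).copy()
    pts = np.column_stack([xs, ys])
    try:
        h = ConvexHull(pts)
    except QhullError:  # collinear points: the hull is the points themselves
        return ys.astype(float).copy()
    v = list(h.vertices)  # counterclockwise
    li = int(np.argmin(xs[v]))
    ri = int(np.argmax(xs[v]))
    chain = []
    i = li
    while True:  # leftmost -> counterclockwise -> rightmost is the lower chain
        chain.append(v[i])
        if i == ri:
            break
        i = (i + 1) % len(v)
    cx = xs[chain]
    cy = ys[chain]
    order = np.argsort(cx)
    return np.interp(xs, cx[order], cy[order])


def dip_reference_qhull(values):
    """Second reference: per-mode prefix hulls each computed from scratch with
    qhull (no incremental updates); practical up to n of a few hundred."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    xs, first = np.unique(x, return_index=True)
    m = len(xs)
    if m == 1:
        return 0.0
    counts = np.diff(np.append(first, n))
    bmin = first.astype(float)
    bmax = (first + counts - 1).astype(float)

    def side(xs_, bmin_, bmax_):
        rel = np.empty(m)
        full = np.empty(m)
        for k in range(m):
            hull = _lower_hull_vals(xs_[: k + 1], bmin_[: k + 1])
            dev = bmax_[: k + 1] + 1.0 - hull
            rel[k] = dev[:k].max() if k else 0.0
            full[k] = dev.max()
        return rel, full

    l_rel, l_full = side(xs, bmin, bmax)
    r_rel_m, r_full_m = side(-xs[::-1], (n - 1 - bmax)[::-1], (n - 1 - bmin)[::-1])
    r_rel, r_full = r_rel_m[::-1], r_full_m[::-1]
    at_point = np.maximum(l_rel, r_rel).min()
    between = np.maximum(l_full[:-1], r_full[1:]).min()
    return float(min(at_point, between)) / (2.0 * n)
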