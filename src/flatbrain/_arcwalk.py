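"""Compiled kernels for walking equal Euclidean steps along a piecewise curve.

A piecewise Bézier chain of ``nseg`` segments (each of order <= 5) is flattened
into a single parameter u in [0, nseg]: segment index = floor(u), local
parameter t = u - floor(u). Segments are stored as power-basis coefficients
padded to degree 5 (higher coefficients zero), so evaluation is a fixed-length
Horner loop that numba compiles to tight machine code.

The walk advances a fixed Euclidean (chord) distance s per step; the parameter
increment for each step is found by binary search on u, bracketing the first
crossing of the chord distance. Steps cross segment joins transparently because
u is global.
"""

import numpy as np
from numba import njit

__all__ = ["walk"]


@njit(cache=True)
def _point(coeffs, nseg, u):
    j = int(np.floor(u))
    if j < 0:
        j = 0
    if j > nseg - 1:
        j = nseg - 1
    t = u - j
    x = coeffs[j, 5, 0]
    y = coeffs[j, 5, 1]
    for k in range(4, -1, -1):
        x = x * t + coeffs[j, k, 0]
        y = y * t + coeffs[j, k, 1]
    return x, y


@njit(cache=True)
def _speed(coeffs, nseg, u):
    j = int(np.floor(u))
    if j < 0:
        j = 0
    if j > nseg - 1:
        j = nseg - 1
    t = u - j
    # derivative of the degree-5 power polynomial
    dx = 5.0 * coeffs[j, 5, 0]
    dy = 5.0 * coeffs[j, 5, 1]
    for k in range(4, 0, -1):
        dx = dx * t + k * coeffs[j, k, 0]
        dy = dy * t + k * coeffs[j, k, 1]
    return np.sqrt(dx * dx + dy * dy)


@njit(cache=True)
def _step(coeffs, nseg, u0, px, py, s, tol, max_iter):
    """First u > u0 where |P(u) - (px,py)| reaches s. Returns (u, ok)."""
    speed = _speed(coeffs, nseg, u0)
    if speed < 1e-12:
        speed = 1e-12
    inc = 0.25 * s / speed
    if inc > 0.05:
        inc = 0.05
    if inc < 1e-7:
        inc = 1e-7
    lo = u0
    hi = u0
    found = False
    while hi < nseg:
        hi = hi + inc
        if hi > nseg:
            hi = nseg
        x, y = _point(coeffs, nseg, hi)
        d = np.sqrt((x - px) ** 2 + (y - py) ** 2)
        if d >= s:
            found = True
            break
        lo = hi
    if not found:
        return float(nseg), False
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        x, y = _point(coeffs, nseg, mid)
        d = np.sqrt((x - px) ** 2 + (y - py) ** 2)
        if abs(d - s) < tol:
            return mid, True
        if d < s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


@njit(cache=True)
def walk(coeffs, nseg, s, N, tol, max_iter):
    """Take up to N chord steps of length s from the curve start.

    Returns (points, u_params, steps_done, gap) where gap is the signed
    convergence measure for the outer spacing search: if all N steps fit,
    gap >= 0 is the chord distance from the final point to the curve end;
    if the curve ran out after k steps, gap < 0 measures the total shortfall.
    """
    pts = np.empty((N + 1, 2))
    us = np.empty(N + 1)
    x, y = _point(coeffs, nseg, 0.0)
    pts[0, 0] = x
    pts[0, 1] = y
    us[0] = 0.0
    u = 0.0
    ex, ey = _point(coeffs, nseg, float(nseg))
    for i in range(N):
        u2, ok = _step(coeffs, nseg, u, x, y, s, tol, max_iter)
        if not ok:
            d_end = np.sqrt((ex - x) ** 2 + (ey - y) ** 2)
            gap = -((N - 1 - i) * s + (s - d_end))
            return pts, us, i, gap
        u = u2
        x, y = _point(coeffs, nseg, u)
        pts[i + 1, 0] = x
        pts[i + 1, 1] = y
        us[i + 1] = u
    gap = np.sqrt((ex - x) ** 2 + (ey - y) ** 2)
    return pts, us, N, gap
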