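"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the chord walk operates
on a dense polyline sampled from the curve, and the rotation oracle evaluates
the sum-of-squares objective on an exhaustive angle grid.
"""

import numpy as np
from numba import njit

from flatbrain.curves import PiecewiseCurve, PointSequence, fit_piecewise


@njit(cache=True)
def polyline_chord_walk(poly, s, N):
    """Walk N Euclidean steps of length s along a dense polyline.

    From the current location, scan forward for the first polyline vertex at
    distance >= s and bisect within that edge for the exact crossing.
    """
    out = np.empty((N + 1, 2))
    out[0] = poly[0]
    px, py = poly[0, 0], poly[0, 1]
    j = 1
    n = len(poly)
    for i in range(N):
        while j < n:
            d = np.sqrt((poly[j, 0] - px) ** 2 + (poly[j, 1] - py) ** 2)
            if d >= s:
                break
            j += 1
        if j >= n:
            out[i + 1, 0] = poly[n - 1, 0]
            out[i + 1, 1] = poly[n - 1, 1]
            continue
        ax, ay = poly[j - 1, 0], poly[j - 1, 1]
        bx, by = poly[j, 0], poly[j, 1]
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            mx = ax + mid * (bx - ax)
            my = ay + mid * (by - ay)
            if np.sqrt((mx - px) ** 2 + (my - py) ** 2) < s:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        px = ax + t * (bx - ax)
        py = ay + t * (by - ay)
        out[i + 1, 0] = px
        out[i + 1, 1] = py
    return out


def dense_walk_oracle(curve: PiecewiseCurve, s: float, N: int,
                      n_dense: int = 100_000) -> np.ndarray:
    """Spec oracle: densely sample the curve, then walk chord lengths."""
    u = np.linspace(0.0, curve.n_segments, n_dense)
    return polyline_chord_walk(curve.point(u), s, N)


def random_smooth_curve(rng, n_points=None, max_group=4) -> PiecewiseCurve:
    """A random gently turning piecewise curve (a plausible anatomical trace)."""
    if n_points is None:
        n_points = int(rng.integers(7, 20))
    heading = rng.uniform(0, 2 * np.pi)
    pts = [np.array([0.0, 0.0])]
    for _ in range(n_points - 1):
        heading += rng.uniform(-0.4, 0.4)
        step = rng.uniform(5.0, 25.0)
        pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
    seq = PointSequence.from_points(np.asarray(pts), max_group=max_group)
    return fit_piecewise(seq)


def rotation_grid_oracle(q, p, center, step_deg=0.001):
    """Exhaustive grid search for the rigid rotation about a fixed center.

    The objective sum |R(q-c)+c-p|^2 expands to A - 2(C cos t + S sin t), so
    the grid evaluation is exact and cheap.
    """
    qc = q - center
    pc = p - center
    C = float(np.sum(qc * pc))
    S = float(np.sum(qc[:, 0] * pc[:, 1] - qc[:, 1] * pc[:, 0]))
    grid = np.deg2rad(np.arange(-180.0, 180.0, step_deg))
    obj = -(C * np.cos(grid) + S * np.sin(grid))
    return float(grid[np.argmin(obj)])
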