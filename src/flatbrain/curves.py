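"""Piecewise Bézier curve fitting and equally spaced sampling frames.

The anatomist marks ordered points along a feature line (the pial surface, a
laminar boundary) in each slice image. Points are grouped into consecutive runs
of 2-6; each run of m points determines a Bézier segment of order m-1 that
interpolates the run exactly when parameters are assigned by normalized
cumulative chord length (m unknown control points, m constraints). Segments are
chained end-to-end, then the control point adjacent to each join on each side is
nudged so that the tangent directions agree (gradient-continuous chain).

Sampling: N+1 equally spaced locations are laid along the curve by a numerical
walk — a candidate spacing s (straight-line distance from first to last curve
point divided by N) is advanced step by step, each step's parameter increment
found by binary search; s is then adjusted (doubling/halving, then bisection)
until exactly N+1 locations fit with the last one landing on the curve end.
Unit normals at those locations, rotated toward the tissue, bound quadrilateral
sampling boxes over a depth window.

Image coordinate convention: origin top-left, x right, y down, pixel centers at
integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from . import _arcwalk
from .errors import (
    DegenerateGeometryError,
    DegenerateParameterizationError,
    InvalidInputError,
    NumericalError,
)

__all__ = [
    "PointSequence",
    "BezierSegment",
    "PiecewiseCurve",
    "CurveFrames",
    "fit_bezier_segment",
    "fit_piecewise",
    "arc_positions",
    "equally_spaced",
    "unit_normals",
    "make_sample_boxes",
    "sample_frames",
]

MAX_GROUP_SIZE = 6  # order-5 segments at most; best fits come from low orders

# ---------------------------------------------------------------------------
# point sequences


@dataclass
class PointSequence:
    """Ordered user points partitioned into groups sharing boundary points.

    ``boundaries`` holds group start indices plus the final index: group k is
    ``points[boundaries[k] : boundaries[k+1] + 1]`` (inclusive), so consecutive
    groups share exactly one point.
    """

    points: np.ndarray  # (n, 2) float
    boundaries: np.ndarray  # (G+1,) int, boundaries[0]=0, boundaries[-1]=n-1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("points must be an (n, 2) array")
        n = len(self.points)
        if n < 2:
            raise InvalidInputError("a point sequence needs at least 2 points")
        b = self.boundaries
        if b[0] != 0 or b[-1] != n - 1 or np.any(np.diff(b) < 1):
            raise InvalidInputError("invalid group boundaries")
        if np.any(np.diff(b) > MAX_GROUP_SIZE - 1):
            raise InvalidInputError(
                f"groups may contain at most {MAX_GROUP_SIZE} points"
            )
        for k in range(len(b) - 1):
            g = self.points[b[k] : b[k + 1] + 1]
            if np.any(np.all(np.diff(g, axis=0) == 0.0, axis=1)):
                raise DegenerateParameterizationError(
                    f"coincident consecutive points in group {k}"
                )

    @classmethod
    def from_points(cls, points, max_group: int = MAX_GROUP_SIZE) -> "PointSequence":
        """Auto-group an ordered point list into runs of up to ``max_group``."""
        points = np.asarray(points, dtype=float)
        n = len(points)
        if n < 2:
            raise InvalidInputError("need at least 2 points")
        if not 2 <= max_group <= MAX_GROUP_SIZE:
            raise InvalidInputError("max_group must be between 2 and 6")
        step = max_group - 1
        b = list(range(0, n - 1, step)) + [n - 1]
        if len(b) >= 2 and b[-1] == b[-2]:
            b.pop(-2)
        return cls(points, np.asarray(b))

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) - 1

    def group(self, k: int) -> np.ndarray:
        return self.points[self.boundaries[k] : self.boundaries[k + 1] + 1]


# ---------------------------------------------------------------------------
# Bézier segments


def _bernstein_matrix(n: int, t: np.ndarray) -> np.ndarray:
    """(len(t), n+1) matrix of Bernstein basis values B_{i,n}(t)."""
    t = np.asarray(t, dtype=float)[:, None]
    i = np.arange(n + 1)[None, :]
    return comb(n, i) * t**i * (1.0 - t) ** (n - i)


def _bernstein_to_power(control: np.ndarray) -> np.ndarray:
    """Convert control points (n+1, 2) to power-basis coefficients (n+1, 2)."""
    n = len(control) - 1
    a = np.zeros_like(control)
    for k in range(n + 1):
        for i in range(k + 1):
            a[k] += control[i] * ((-1.0) ** (k - i)) * comb(n, i) * comb(n - i, k - i)
    return a


@dataclass
class BezierSegment:
    """A single Bézier segment of order ``len(control) - 1``."""

    control: np.ndarray  # (order+1, 2)
    _coeffs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        if self.control.ndim != 2 or self.control.shape[1] != 2 or len(self.control) < 2:
            raise InvalidInputError("control must be an (order+1, 2) array, order >= 1")
        self._coeffs = _bernstein_to_power(self.control)

    @property
    def order(self) -> int:
        return len(self.control) - 1

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        n = self.order
        out = np.zeros((len(t), 2))
        for k in range(n, -1, -1):
            out = out * t + self._coeffs[k]
        return out

    def derivative(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        n = self.order
        out = np.zeros((len(t), 2))
        for k in range(n, 0, -1):
            out = out * t + k * self._coeffs[k]
        return out


def chord_length_parameters(points: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord-length parameters in [0, 1]."""
    points = np.asarray(points, dtype=float)
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(d == 0.0):
        raise DegenerateParameterizationError("coincident consecutive points")
    t = np.concatenate([[0.0], np.cumsum(d)])
    return t / t[-1]


def fit_bezier_segment(points) -> BezierSegment:
    """Fit the order-(m-1) Bézier segment interpolating m ordered points.

    Parameters are assigned by normalized cumulative chord length, which makes
    the least-squares system square: the fit interpolates every input point and
    the endpoints coincide with the first and last points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise InvalidInputError("points must be an (m, 2) array")
    m = len(points)
    if m < 2:
        raise InvalidInputError("need at least 2 points to fit a segment")
    t = chord_length_parameters(points)
    B = _bernstein_matrix(m - 1, t)
    control = np.linalg.solve(B, points)
    # endpoints are pinned by construction (B rows at t=0,1 are unit vectors);
    # re-assert exactly to kill last-bit solver noise
    control[0] = points[0]
    control[-1] = points[-1]
    return BezierSegment(control)


# ---------------------------------------------------------------------------
# piecewise curves


def _smooth_joins(segments: list[BezierSegment]) -> list[BezierSegment]:
    """Equalize tangent directions at each join.

    At a join, the interior control point nearest the join on each side is
    moved onto the bisector of the two incoming tangent directions, keeping its
    distance from the join. An order-1 side has no interior control point; the
    flexible side is then aligned to the rigid side's direction instead.
    Idempotent: once the tangents agree their bisector is that shared direction.
    """
    ctrls = [s.control.copy() for s in segments]
    for k in range(len(ctrls) - 1):
        L, R = ctrls[k], ctrls[k + 1]
        join = L[-1]
        tL = join - L[-2]
        tR = R[1] - join
        nL, nR = np.linalg.norm(tL), np.linalg.norm(tR)
        if nL < 1e-14 or nR < 1e-14:
            continue
        uL, uR = tL / nL, tR / nR
        left_free = len(L) >= 3
        right_free = len(R) >= 3
        if left_free and right_free:
            bis = uL + uR
            nb = np.linalg.norm(bis)
            if nb < 1e-12:  # opposing tangents: bisector undefined, leave alone
                continue
            bis /= nb
            L[-2] = join - nL * bis
            R[1] = join + nR * bis
        elif left_free:
            L[-2] = join - nL * uR
        elif right_free:
            R[1] = join + nR * uL
    return [BezierSegment(c) for c in ctrls]


@dataclass
class PiecewiseCurve:
    """Gradient-continuous chain of Bézier segments, parameter u in [0, nseg]."""

    segments: list
    _coeffs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidInputError("a piecewise curve needs at least one segment")
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            if np.linalg.norm(a.control[-1] - b.control[0]) > 1e-9:
                raise InvalidInputError("segments are not positionally continuous")
        co = np.zeros((len(self.segments), 6, 2))
        for j, s in enumerate(self.segments):
            co[j, : s.order + 1] = s._coeffs
        self._coeffs = co

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def _locate(self, u) -> tuple[np.ndarray, np.ndarray]:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        j = np.clip(np.floor(u).astype(int), 0, self.n_segments - 1)
        return j, u - j

    def point(self, u) -> np.ndarray:
        j, t = self._locate(u)
        out = np.zeros((len(t), 2))
        tt = t[:, None]
        for k in range(5, -1, -1):
            out = out * tt + self._coeffs[j, k]
        return out

    def tangent(self, u) -> np.ndarray:
        j, t = self._locate(u)
        out = np.zeros((len(t), 2))
        tt = t[:, None]
        for k in range(5, 0, -1):
            out = out * tt + k * self._coeffs[j, k]
        return out

    @property
    def start(self) -> np.ndarray:
        return self.segments[0].control[0].copy()

    @property
    def end(self) -> np.ndarray:
        return self.segments[-1].control[-1].copy()

    def dense_points(self, per_segment: int = 4096) -> np.ndarray:
        """Dense polyline along the whole chain (for lengths and oracles)."""
        u = np.linspace(0.0, self.n_segments, per_segment * self.n_segments + 1)
        return self.point(u)

    def total_length(self, per_segment: int = 4096) -> float:
        p = self.dense_points(per_segment)
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def fit_piecewise(seq: PointSequence) -> PiecewiseCurve:
    """Fit every group of a point sequence and smooth the joins."""
    segments = [fit_bezier_segment(seq.group(k)) for k in range(seq.n_groups)]
    if len(segments) > 1:
        segments = _smooth_joins(segments)
    return PiecewiseCurve(segments)


# ---------------------------------------------------------------------------
# equal spacing

_T_TOL = 1e-10  # absolute tolerance on the per-step chord-length error (px)
_T_MAX_ITER = 100
_S_REL_TOL = 1e-3  # the final point must land within s * 1e-3 of the curve end
_S_MAX_ITER = 200


def equally_spaced(curve: PiecewiseCurve, N: int):
    """N+1 equally spaced (Euclidean step s) locations along the curve.

    Three-step procedure: a candidate spacing s = |end - start| / N is walked
    along the curve, each step's parameter increment found by binary search;
    if N+1 locations do not fit, s is adjusted by doubling/halving to bracket
    and then bisected until the final location lands within s*1e-3 of the
    curve end. Returns (points (N+1,2), u parameters (N+1,), spacing s).
    """
    if N < 1:
        raise InvalidInputError("N must be >= 1")
    coeffs = curve._coeffs
    nseg = curve.n_segments
    s0 = float(np.linalg.norm(curve.end - curve.start)) / N
    if s0 == 0.0:
        # closed or degenerate chord; fall back to total length estimate
        s0 = curve.total_length(per_segment=256) / N
    if s0 <= 0.0:
        raise InvalidInputError("curve has zero length")

    def trial(s):
        pts, us, done, gap = _arcwalk.walk(coeffs, nseg, s, N, _T_TOL, _T_MAX_ITER)
        return pts, us, done, gap

    pts, us, done, gap = trial(s0)
    if done == N and 0.0 <= gap < s0 * _S_REL_TOL:
        return pts, us, s0

    # bracket by doubling/halving: g(s) decreases with s
    if gap >= 0.0:  # stopped short of the end: s too small
        lo, g_lo, r_lo = s0, gap, (pts, us)
        hi = s0
        for _ in range(60):
            hi *= 2.0
            pts, us, done, gap = trial(hi)
            if gap < 0.0:
                break
            lo, g_lo, r_lo = hi, gap, (pts, us)
        else:
            raise NumericalError("spacing search failed to bracket (doubling)")
    else:
        hi = s0
        lo = s0
        for _ in range(60):
            lo *= 0.5
            pts, us, done, gap = trial(lo)
            if done == N and gap >= 0.0:
                g_lo, r_lo = gap, (pts, us)
                break
        else:
            raise NumericalError("spacing search failed to bracket (halving)")

    # bisection on s; invariant: walk(lo) completes with gap >= 0, walk(hi) overruns
    for _ in range(_S_MAX_ITER):
        if g_lo < lo * _S_REL_TOL:
            pts, us = r_lo
            return pts, us, lo
        mid = 0.5 * (lo + hi)
        pts, us, done, gap = trial(mid)
        if done == N and gap >= 0.0:
            lo, g_lo, r_lo = mid, gap, (pts, us)
        else:
            hi = mid
    raise NumericalError("spacing bisection did not converge")


def arc_positions(curve: PiecewiseCurve, N: int) -> np.ndarray:
    """The N+1 equally spaced on-curve points (convenience wrapper)."""
    pts, _, _ = equally_spaced(curve, N)
    return pts


def unit_normals(curve: PiecewiseCurve, u, tissue_side: int = 1) -> np.ndarray:
    """Unit normals at curve parameters ``u``, rotated toward the tissue.

    The tangent is rotated +90 deg in image coordinates (x right, y down);
    ``tissue_side`` = -1 flips every normal to the other side of the curve.
    """
    if tissue_side not in (1, -1):
        raise InvalidInputError("tissue_side must be +1 or -1")
    tan = curve.tangent(u)
    norms = np.linalg.norm(tan, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("zero-length tangent on curve")
    tan = tan / norms[:, None]
    normal = np.column_stack([-tan[:, 1], tan[:, 0]])
    return tissue_side * normal


@dataclass
class CurveFrames:
    """Equally spaced sample frames: on-curve points plus tissue-side normals."""

    points: np.ndarray  # (N+1, 2) px
    normals: np.ndarray  # (N+1, 2) unit
    u: np.ndarray  # (N+1,) curve parameters
    spacing: float  # px

    @property
    def n_bins(self) -> int:
        return len(self.points) - 1


def sample_frames(curve: PiecewiseCurve, N: int, tissue_side: int = 1) -> CurveFrames:
    pts, us, s = equally_spaced(curve, N)
    normals = unit_normals(curve, us, tissue_side)
    return CurveFrames(points=pts, normals=normals, u=us, spacing=s)


def make_sample_boxes(frames: CurveFrames, d0_um: float, d1_um: float,
                      px_size_um: float) -> np.ndarray:
    """Quadrilateral sampling boxes between adjacent normals, (N, 4, 2) px.

    Box i runs from depth d0 to d1 (µm below the curve, along the normal):
    corners p_i+n_i*d0, p_i+n_i*d1, p_{i+1}+n_{i+1}*d1, p_{i+1}+n_{i+1}*d0.
    """
    if d1_um <= d0_um or d0_um < 0:
        raise InvalidInputError("need d1 > d0 >= 0")
    if px_size_um <= 0:
        raise InvalidInputError("pixel size must be positive")
    a = d0_um / px_size_um
    b = d1_um / px_size_um
    p, n = frames.points, frames.normals
    boxes = np.stack(
        [
            p[:-1] + n[:-1] * a,
            p[:-1] + n[:-1] * b,
            p[1:] + n[1:] * b,
            p[1:] + n[1:] * a,
        ],
        axis=1,
    )
    return boxes
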