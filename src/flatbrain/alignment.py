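"""Rigid alignment of the slice stack.

Slicing scrambles the in-plane placement of consecutive sections. Two cues
restore it: (1) the circular hole left by a needle pushed through the embedding
medium before slicing — three user-marked points on the hole perimeter give a
circumcircle whose center is a common fiducial, so translating every slice's
hole center onto one alignment axis removes the translational jitter; and
(2) the traced curves themselves — starting from the second slice, each slice
is rotated about the alignment axis to minimize the sum of squared distances
between its equally spaced curve locations and those of the previous,
already-aligned slice.

Transforms are applied to sampled data coordinates, never to image rasters.
By convention the alignment axis is parallel to the x (rostro-caudal) axis:
each slice occupies a plane of constant x, and in-plane (y, z) map from image
(column, row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "CircleMark",
    "SliceTransform",
    "circumcircle",
    "translate_to_axis",
    "optimal_rotation",
    "align_stack",
]

log = logging.getLogger(__name__)


@dataclass
class CircleMark:
    """Circumcircle of three perimeter points on the needle hole."""

    points: np.ndarray  # (3, 2)
    center: np.ndarray  # (2,)
    radius: float


def circumcircle(p1, p2, p3) -> CircleMark:
    """Unique circle through three non-collinear points.

    Solves the two perpendicular-bisector equations; raises
    :class:`DegenerateGeometryError` when the triangle area vanishes relative
    to the points' scale.
    """
    pts = np.asarray([p1, p2, p3], dtype=float)
    a, b, c = pts
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), np.linalg.norm(c - b))
    u, v = b - a, c - a
    area2 = abs(u[0] * v[1] - u[1] * v[0])  # twice the triangle area
    if scale == 0.0 or area2 < 1e-12 * scale**2:
        raise DegenerateGeometryError("circle-mark points are collinear")
    # perpendicular bisectors: 2(b-a).x = |b|^2-|a|^2 ; 2(c-a).x = |c|^2-|a|^2
    A = 2.0 * np.array([b - a, c - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a])
    center = np.linalg.solve(A, rhs)
    radius = float(np.linalg.norm(a - center))
    return CircleMark(pts, center, radius)


@dataclass
class SliceTransform:
    """In-plane rigid motion: translate, then rotate about a fixed center.

    ``apply`` maps points p to R_theta(p + t - c) + c where c is the
    alignment-axis point (the post-translation hole center).
    """

    translation: np.ndarray  # (2,)
    rotation: float  # radians
    center: np.ndarray  # (2,)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        return (pts + self.translation - self.center) @ R.T + self.center


def translate_to_axis(centers: list, axis_point=None) -> np.ndarray:
    """Per-slice offsets placing every hole center on the alignment axis.

    ``centers`` holds one hole center per slice (None marks a missing circle
    mark, reported collectively). The axis point defaults to the first slice's
    hole center; after applying the offsets all hole centers coincide there.
    """
    missing = [i for i, c in enumerate(centers) if c is None]
    if missing:
        raise InvalidInputError(f"missing circle marks on slices {missing}")
    centers = np.asarray([np.asarray(c, dtype=float) for c in centers])
    if axis_point is None:
        axis_point = centers[0]
    return np.asarray(axis_point, dtype=float)[None, :] - centers


def _ssd(theta: float, q: np.ndarray, p: np.ndarray, center: np.ndarray) -> float:
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    moved = (q - center) @ R.T + center
    return float(np.sum((moved - p) ** 2))


def optimal_rotation(curve: np.ndarray, curve_prev: np.ndarray, center) -> float:
    """Rotation about ``center`` best matching one slice's curve to the previous.

    Minimizes the sum of squared distances between corresponding equally
    spaced curve locations over theta in (-pi, pi]: a 1-degree coarse grid
    locates the basin, golden-section refines to 1e-6 rad. Grid ties are
    broken toward the smaller |theta|.
    """
    q = np.asarray(curve, dtype=float)
    p = np.asarray(curve_prev, dtype=float)
    if q.shape != p.shape or q.ndim != 2 or q.shape[1] != 2:
        raise InvalidInputError("curves must be equal-shaped (N+1, 2) arrays")
    center = np.asarray(center, dtype=float)
    grid = np.deg2rad(np.arange(-179.0, 181.0, 1.0))
    vals = np.array([_ssd(t, q, p, center) for t in grid])
    best = vals.min()
    ties = np.flatnonzero(vals <= best * (1.0 + 1e-12) + 1e-30)
    t0 = grid[ties[np.argmin(np.abs(grid[ties]))]]
    lo, hi = t0 - np.deg2rad(1.5), t0 + np.deg2rad(1.5)
    try:
        res = minimize_scalar(
            _ssd, args=(q, p, center), bracket=(lo, t0, hi),
            method="golden", options={"xtol": 1e-9},
        )
    except ValueError:
        # flat objective around the grid minimum; fall back to bounded search
        res = minimize_scalar(
            _ssd, args=(q, p, center), bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-8},
        )
    theta = float(res.x)
    # wrap to (-pi, pi]
    if theta <= -np.pi:
        theta += 2 * np.pi
    elif theta > np.pi:
        theta -= 2 * np.pi
    return theta


def align_stack(curves: list, centers: list | None) -> list[SliceTransform]:
    """Sequentially align a stack of sampled curves.

    ``curves`` holds one (K, 2) array of equally spaced curve locations per
    slice (all layers concatenated is fine, as long as K matches across
    slices). ``centers`` holds the per-slice hole centers; when None, a
    curve-only fallback anchors translations on curve centroids (logged).
    Slice 0 keeps rotation 0; each later slice is rotated about the alignment
    axis to best match the previous aligned slice.
    """
    M = len(curves)
    if M < 1:
        raise InvalidInputError("empty stack")
    K = curves[0].shape[0]
    bad = [i for i, c in enumerate(curves) if c.shape != (K, 2)]
    if bad:
        raise InvalidInputError(
            f"slices {bad} have a different number of curve locations than slice 0; "
            "re-sample all slices with the same N"
        )
    if centers is None:
        log.warning("no circle marks available: using curve-centroid fallback "
                    "for slice translations")
        cents = [np.mean(c, axis=0) for c in curves]
    else:
        cents = centers
    offsets = translate_to_axis(cents)
    axis_point = np.asarray(cents[0], dtype=float)
    transforms = [SliceTransform(offsets[0], 0.0, axis_point)]
    prev = transforms[0].apply(curves[0])
    for i in range(1, M):
        shifted = curves[i] + offsets[i]
        theta = optimal_rotation(shifted, prev, axis_point)
        tr = SliceTransform(offsets[i], theta, axis_point)
        transforms.append(tr)
        prev = tr.apply(curves[i])
    return transforms
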