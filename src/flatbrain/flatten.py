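"""3D surface assembly and digital unwrapping into a 2D flat map.

After alignment, each slice contributes an expression ribbon: N+1 equally
spaced 3D curve points (the slice plane sits at x = slice_index * thickness)
plus N sampled expression values. Connecting bin j of slice i to bin j of
slice i+1 meshes the ribbons into a surface. A user-defined brain axis (a 3D
line through the axis marks of the first and last slices) and an angle phi
about it define a center line of zero marks — the most distal curve point at
that angle on each slice. Unwrapping straightens each ribbon while pinning it
at its zero mark: the map's u-coordinate is the signed cumulative 3D arc
length from the zero mark (negative toward the curve start), the v-coordinate
is the slice position. Arc length is conserved exactly per ribbon, so the
flat map is composed of irregularly sized quadrilateral data pixels.

Internally everything is µm; flat maps are emitted in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Surface3D",
    "FlatMap",
    "build_surface",
    "find_zero_marks",
    "unwrap",
    "project_point_to_map",
    "smooth_mesh_for_display",
    "save_flatmap",
    "load_flatmap",
]

UM_PER_MM = 1000.0


@dataclass
class Surface3D:
    """Per-slice ribbons meshed into a surface, with the brain axis."""

    points: np.ndarray  # (M, N+1, 3) µm; [:, :, 0] is the slice x-position
    values: np.ndarray  # (M, N) expression per bin (NaN = missing)
    axis_points: np.ndarray  # (M, 3) µm, brain-axis point in each slice plane

    def __post_init__(self) -> None:
        M, K, _ = self.points.shape
        if self.values.shape != (M, K - 1):
            raise InvalidInputError("values must be (M, N) for (M, N+1, 3) points")
        if self.axis_points.shape != (M, 3):
            raise InvalidInputError("need one axis point per slice")

    @property
    def n_slices(self) -> int:
        return self.points.shape[0]

    @property
    def n_bins(self) -> int:
        return self.points.shape[1] - 1


@dataclass
class FlatMap:
    """Digitally unwrapped surface: irregular quadrilateral data pixels (mm)."""

    quads: np.ndarray  # (P, 4, 2) corner coordinates (u, v) in mm
    values: np.ndarray  # (P,)
    slice_idx: np.ndarray  # (P,) lower slice of each quad
    bin_idx: np.ndarray  # (P,)
    outline: np.ndarray  # (K, 2) cortex outline polygon, mm
    u_edges: np.ndarray  # (M, N+1) per-slice flattened bin-edge coordinates, mm
    v: np.ndarray  # (M,) per-slice map ordinate, mm
    landmarks: dict = field(default_factory=dict)  # name -> (2,) mm


def build_surface(curve_points_2d: list, values: np.ndarray,
                  axis_marks_2d: tuple, slice_positions_um: np.ndarray,
                  pixel_size_um: float) -> Surface3D:
    """Lift aligned per-slice curves into 3D and attach the brain axis.

    ``curve_points_2d``: per slice, the aligned (N+1, 2) sampled curve in px.
    ``axis_marks_2d``: the aligned axis marks of the first and last slices
    (px). The brain axis is the 3D line through those two marks lifted to
    their slice planes, linearly interpolated across slices.
    """
    M = len(curve_points_2d)
    if M < 2:
        raise InvalidInputError("need at least 2 slices to build a surface")
    if axis_marks_2d[0] is None or axis_marks_2d[1] is None:
        raise InvalidInputError("axis marks missing on the first/last slice")
    K = curve_points_2d[0].shape[0]
    pts = np.empty((M, K, 3))
    x = np.asarray(slice_positions_um, dtype=float)
    for i, c in enumerate(curve_points_2d):
        if c.shape != (K, 2):
            raise InvalidInputError("all slices must share the same N")
        pts[i, :, 0] = x[i]
        pts[i, :, 1:] = c * pixel_size_um
    a0 = np.asarray(axis_marks_2d[0], dtype=float) * pixel_size_um
    a1 = np.asarray(axis_marks_2d[1], dtype=float) * pixel_size_um
    frac = (x - x[0]) / (x[-1] - x[0])
    axis_points = np.empty((M, 3))
    axis_points[:, 0] = x
    axis_points[:, 1:] = a0[None, :] + frac[:, None] * (a1 - a0)[None, :]
    return Surface3D(pts, np.asarray(values, dtype=float), axis_points)


def _slice_angles(surface: Surface3D, i: int) -> tuple[np.ndarray, np.ndarray]:
    """In-plane angle and radius of each curve sample about the axis point.

    The angle is measured in the slice (y, z) plane with the anatomical 'up'
    positive: angle = atan2(-dz, dy), so a sample straight above the axis in
    the image (smaller row) sits at +pi/2.
    """
    d = surface.points[i, :, 1:] - surface.axis_points[i, 1:][None, :]
    ang = np.arctan2(-d[:, 1], d[:, 0])
    rad = np.linalg.norm(d, axis=1)
    return ang, rad


def find_zero_marks(surface: Surface3D, phi: float) -> np.ndarray:
    """Index of the zero mark on each slice: the most distal curve sample at
    angle ``phi`` about the brain axis.

    The sample whose angular position is nearest phi is chosen; ties (within
    1e-12 rad) break toward the larger radial distance. If no sample lies
    within pi/2 of phi the surface does not subtend the requested angle.
    """
    if not -np.pi < phi <= np.pi:
        raise InvalidInputError("phi must lie in (-pi, pi]")
    idx = np.empty(surface.n_slices, dtype=int)
    for i in range(surface.n_slices):
        ang, rad = _slice_angles(surface, i)
        diff = np.abs(np.angle(np.exp(1j * (ang - phi))))
        dmin = diff.min()
        if dmin > np.pi / 2:
            raise InvalidInputError(
                f"slice {i}: curve subtends no angle within pi/2 of phi"
            )
        cand = np.flatnonzero(diff <= dmin + 1e-12)
        idx[i] = cand[np.argmax(rad[cand])]
    return idx


def unwrap(surface: Surface3D, zero_marks: np.ndarray) -> FlatMap:
    """Straighten each ribbon about its zero mark into a 2D flat map.

    u(bin edge k) = signed cumulative 3D arc length from the zero mark
    (negative toward the curve start), v = slice x-position; both in mm.
    Total ribbon length is conserved exactly.
    """
    M, K = surface.n_slices, surface.n_bins + 1
    zero_marks = np.asarray(zero_marks, dtype=int)
    if zero_marks.shape != (M,):
        raise InvalidInputError("need one zero mark per slice")
    u = np.empty((M, K))
    for i in range(M):
        seg = np.linalg.norm(np.diff(surface.points[i], axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        u[i] = (cum - cum[zero_marks[i]]) / UM_PER_MM
    v = surface.points[:, 0, 0] / UM_PER_MM

    quads = []
    vals = []
    sidx = []
    bidx = []
    for i in range(M - 1):
        for k in range(K - 1):
            quads.append([
                (u[i, k], v[i]),
                (u[i, k + 1], v[i]),
                (u[i + 1, k + 1], v[i + 1]),
                (u[i + 1, k], v[i + 1]),
            ])
            vals.append(surface.values[i, k])
            sidx.append(i)
            bidx.append(k)
    outline = np.concatenate([
        np.column_stack([u[0], np.full(K, v[0])]),
        np.column_stack([u[1:, -1], v[1:]]),
        np.column_stack([u[-1, ::-1][1:], np.full(K - 1, v[-1])]),
        np.column_stack([u[-2::-1, 0], v[-2::-1]]),
    ])[:-1]
    return FlatMap(
        quads=np.asarray(quads, dtype=float),
        values=np.asarray(vals, dtype=float),
        slice_idx=np.asarray(sidx, dtype=int),
        bin_idx=np.asarray(bidx, dtype=int),
        outline=outline,
        u_edges=u,
        v=v,
    )


def project_point_to_map(surface: Surface3D, flatmap: FlatMap, slice_i: int,
                         point_2d_px: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Flat-map (u, v) of an aligned in-plane point near the slice's ribbon.

    Used to carry global landmarks into map coordinates: the point is snapped
    to the nearest sampled curve location on its slice.
    """
    p = np.asarray(point_2d_px, dtype=float) * pixel_size_um
    d = np.linalg.norm(surface.points[slice_i, :, 1:] - p[None, :], axis=1)
    k = int(np.argmin(d))
    return np.array([flatmap.u_edges[slice_i, k], flatmap.v[slice_i]])


def save_flatmap(fm: FlatMap, path, group: str = "flatmap") -> None:
    """Store a flat map in an HDF5 file (one group per layer)."""
    import h5py

    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name in ("quads", "values", "slice_idx", "bin_idx", "outline",
                     "u_edges", "v"):
            g.create_dataset(name, data=getattr(fm, name))
        lm = g.create_group("landmarks")
        for k, pt in fm.landmarks.items():
            lm.create_dataset(k, data=np.asarray(pt, dtype=float))


def load_flatmap(path, group: str = "flatmap") -> FlatMap:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        return FlatMap(
            quads=np.asarray(g["quads"]),
            values=np.asarray(g["values"]),
            slice_idx=np.asarray(g["slice_idx"]),
            bin_idx=np.asarray(g["bin_idx"]),
            outline=np.asarray(g["outline"]),
            u_edges=np.asarray(g["u_edges"]),
            v=np.asarray(g["v"]),
            landmarks={k: np.asarray(v) for k, v in g["landmarks"].items()},
        )


def smooth_mesh_for_display(points: np.ndarray, iterations: int = 2,
                            weight: float = 0.5) -> np.ndarray:
    """Laplacian smoothing of the (M, N+1, 3) mesh, for visualization only.

    Analysis never uses the smoothed coordinates; this mirrors the smoothed
    surface rendering of the 3D viewer.
    """
    p = np.asarray(points, dtype=float).copy()
    for _ in range(iterations):
        nb = np.zeros_like(p)
        cnt = np.zeros(p.shape[:2])[..., None]
        nb[1:] += p[:-1]
        cnt[1:] += 1
        nb[:-1] += p[1:]
        cnt[:-1] += 1
        nb[:, 1:] += p[:, :-1]
        cnt[:, 1:] += 1
        nb[:, :-1] += p[:, 1:]
        cnt[:, :-1] += 1
        p = (1 - weight) * p + weight * nb / cnt
    return p
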