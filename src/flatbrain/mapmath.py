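"""Flat-map registration and scattered-to-grid resampling.

Maps from different brains are compared in the frame of an arbitrarily chosen
reference brain. Three landmarks placed at the same morphological locations on
each brain determine a unique 2D affine transform (6 equations, 6 unknowns)
projecting one map's landmark triplet onto the reference triplet; the transform
is applied to every data-pixel corner.

Because a transformed flat map is composed of irregularly sized quadrilateral
data pixels, it is resampled onto a Cartesian grid of square pixels: each quad
spreads its value with an elliptical Gaussian kernel centered at the quad
centroid, principal axes along the quad's mean edge directions and sigma equal
to half the mean side length per axis; grid values are weight-normalized sums
and a validity mask keeps pixels that collected at least a minimum weight mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .errors import DegenerateGeometryError, InvalidInputError
from .flatten import FlatMap

__all__ = [
    "AffineTransform2D",
    "GridMap",
    "affine_from_triplets",
    "apply_affine",
    "grid_geometry",
    "regrid",
    "common_mask",
    "save_grid",
    "load_grid",
]

MASK_THRESHOLD = 1e-3  # minimum accumulated weight (units of one kernel peak)


@dataclass
class AffineTransform2D:
    """p -> A p + b with invertible A."""

    A: np.ndarray  # (2, 2)
    b: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if abs(np.linalg.det(self.A)) < 1e-15:
            raise InvalidInputError("affine transform is singular")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.A.T + self.b

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.b)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))


def _triplet_ok(t: np.ndarray) -> bool:
    a, b, c = t
    u, v = b - a, c - a
    return abs(u[0] * v[1] - u[1] * v[0]) > 2e-9  # twice the 1e-9 mm^2 area floor


def affine_from_triplets(src, dst) -> AffineTransform2D:
    """The unique affine mapping three landmark pairs exactly.

    Both triplets must be non-collinear; the 6x6 linear system is solved in
    homogeneous form and each landmark is reproduced to < 1e-9 mm.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (3, 2) or dst.shape != (3, 2):
        raise InvalidInputError("landmark triplets must be (3, 2) arrays")
    if not (_triplet_ok(src) and _triplet_ok(dst)):
        raise DegenerateGeometryError("landmark triplet is collinear")
    H = np.column_stack([src, np.ones(3)])  # (3, 3)
    X = np.linalg.solve(H, dst)  # (3, 2): [A.T; b]
    return AffineTransform2D(X[:2].T, X[2])


def apply_affine(flatmap: FlatMap, T: AffineTransform2D) -> FlatMap:
    """Transform every data-pixel corner (and outline, landmarks); values kept."""
    return FlatMap(
        quads=T.apply(flatmap.quads.reshape(-1, 2)).reshape(flatmap.quads.shape),
        values=flatmap.values.copy(),
        slice_idx=flatmap.slice_idx.copy(),
        bin_idx=flatmap.bin_idx.copy(),
        outline=T.apply(flatmap.outline),
        u_edges=flatmap.u_edges.copy(),
        v=flatmap.v.copy(),
        landmarks={k: T.apply(v) for k, v in flatmap.landmarks.items()},
    )


@dataclass
class GridMap:
    """Cartesian raster of expression with a validity mask (square pixels)."""

    values: np.ndarray  # (H, W) float
    mask: np.ndarray  # (H, W) bool
    pixel_mm: float
    origin: np.ndarray  # (2,) mm: map coordinates of pixel center [0, 0]

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.values.shape
        xs = self.origin[0] + self.pixel_mm * np.arange(w)
        ys = self.origin[1] + self.pixel_mm * np.arange(h)
        return xs, ys

    def same_geometry(self, other: "GridMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.pixel_mm, other.pixel_mm)
            and np.allclose(self.origin, other.origin)
        )


def grid_geometry(maps, pixel_mm: float, anchor=None, pad_mm: float = 0.5):
    """Shared (origin, shape) covering one or more flat maps.

    The origin is snapped so that ``anchor`` (typically the reference map's
    first landmark) lies exactly on a pixel center, making overlays
    reproducible across runs.
    """
    if pixel_mm <= 0:
        raise InvalidInputError("pixel_mm must be positive")
    corners = np.concatenate([m.quads.reshape(-1, 2) for m in maps])
    lo = corners.min(axis=0) - pad_mm
    hi = corners.max(axis=0) + pad_mm
    if anchor is None:
        anchor = np.zeros(2)
    anchor = np.asarray(anchor, dtype=float)
    origin = anchor + pixel_mm * np.floor((lo - anchor) / pixel_mm)
    shape = tuple(np.ceil((hi - origin) / pixel_mm).astype(int) + 1)  # (W, H) order
    return origin, (shape[1], shape[0])


def regrid(flatmap: FlatMap, pixel_mm: float, origin=None, shape=None,
           sigma_mult: float = 1.0, mask_threshold: float = MASK_THRESHOLD) -> GridMap:
    """Resample irregular quadrilateral data pixels onto a square-pixel grid.

    Each quad contributes its value to nearby grid pixels with elliptical
    Gaussian weights (axes along the quad's mean edge directions, sigma =
    sigma_mult * half the mean side length per axis). Grid value = weighted
    mean; mask = accumulated weight >= ``mask_threshold`` (in units of a unit
    kernel's peak mass). Linear in the data values and exact on constants.
    """
    if pixel_mm <= 0:
        raise InvalidInputError("pixel_mm must be positive")
    if len(flatmap.values) == 0:
        raise InvalidInputError("flat map is empty")
    if origin is None or shape is None:
        origin, shape = grid_geometry([flatmap], pixel_mm)
    origin = np.asarray(origin, dtype=float)
    H, W = shape
    wsum = np.zeros((H, W))
    vsum = np.zeros((H, W))

    quads = flatmap.quads
    values = flatmap.values
    centroids = quads.mean(axis=1)
    # mean edge directions: u-like edges (c0->c1, c3->c2), v-like (c0->c3, c1->c2)
    e_u = 0.5 * ((quads[:, 1] - quads[:, 0]) + (quads[:, 2] - quads[:, 3]))
    e_v = 0.5 * ((quads[:, 3] - quads[:, 0]) + (quads[:, 2] - quads[:, 1]))
    for g, eu, ev, val in zip(centroids, e_u, e_v, values):
        if not np.isfinite(val):
            continue
        lu, lv = np.linalg.norm(eu), np.linalg.norm(ev)
        if lu < 1e-12 or lv < 1e-12:
            continue
        su = max(sigma_mult * lu / 2.0, 1e-9)
        sv = max(sigma_mult * lv / 2.0, 1e-9)
        uu, vv = eu / lu, ev / lv
        cov = su**2 * np.outer(uu, uu) + sv**2 * np.outer(vv, vv)
        prec = np.linalg.inv(cov)
        r = 4.0 * max(su, sv)
        i0 = max(0, int(np.floor((g[1] - r - origin[1]) / pixel_mm)))
        i1 = min(H - 1, int(np.ceil((g[1] + r - origin[1]) / pixel_mm)))
        j0 = max(0, int(np.floor((g[0] - r - origin[0]) / pixel_mm)))
        j1 = min(W - 1, int(np.ceil((g[0] + r - origin[0]) / pixel_mm)))
        if i0 > i1 or j0 > j1:
            continue
        xs = origin[0] + pixel_mm * np.arange(j0, j1 + 1) - g[0]
        ys = origin[1] + pixel_mm * np.arange(i0, i1 + 1) - g[1]
        dx, dy = np.meshgrid(xs, ys)
        q = (prec[0, 0] * dx**2 + 2 * prec[0, 1] * dx * dy + prec[1, 1] * dy**2)
        wgt = np.exp(-0.5 * q)
        wsum[i0:i1 + 1, j0:j1 + 1] += wgt
        vsum[i0:i1 + 1, j0:j1 + 1] += wgt * val
    mask = wsum >= mask_threshold
    out = np.full((H, W), np.nan)
    out[mask] = vsum[mask] / wsum[mask]
    return GridMap(out, mask, float(pixel_mm), origin)


def common_mask(grids) -> np.ndarray:
    """Logical AND of the validity masks of geometry-matched grids."""
    grids = list(grids)
    if not grids:
        raise InvalidInputError("no grids given")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise InvalidInputError("grids do not share pixel size/origin/shape")
    mask = first.mask.copy()
    for g in grids[1:]:
        mask &= g.mask
    return mask


def save_grid(grid: GridMap, tiff_path, csv_path=None) -> None:
    """Write a grid as 32-bit float TIFF (NaN outside the mask) plus CSV."""
    tifffile.imwrite(tiff_path, grid.values.astype(np.float32))
    if csv_path is not None:
        xs, ys = grid.centers()
        ii, jj = np.nonzero(grid.mask)
        pd.DataFrame(
            {"u_mm": xs[jj], "v_mm": ys[ii], "value": grid.values[ii, jj]}
        ).to_csv(csv_path, index=False)


def load_grid(tiff_path, pixel_mm: float, origin=(0.0, 0.0)) -> GridMap:
    values = tifffile.imread(tiff_path).astype(float)
    mask = np.isfinite(values)
    return GridMap(values, mask, float(pixel_mm), np.asarray(origin, dtype=float))
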