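"""On-disk project model: slices, curves, marks, landmarks and metadata.

A project bundles an ordered stack of coronal slice records — each referencing
an image file and carrying the user-drawn annotations (per-layer curve points,
needle-hole circle marks, optional axis mark, optional named global landmarks
and freehand loops) — together with the physical metadata needed for
reconstruction (slice thickness, bin count, per-layer depth windows).

The container format is HDF5 with a versioned schema: one group per slice,
datasets for point arrays, attributes for scalars. All physical coordinates
are µm internally; flat maps downstream are reported in mm.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from shapely.geometry import Polygon

from .curves import PointSequence
from .errors import InvalidInputError, ValidationError

__all__ = [
    "SliceRecord",
    "Project",
    "read_project",
    "write_project",
    "trace_area",
    "region_fraction",
]

SCHEMA_VERSION = 1

DEFAULT_THICKNESS_UM = 100.0  # vibratome section thickness
DEFAULT_BIN_COUNT = 150  # medial-to-lateral sampling bins per curve


def _collinear(pts: np.ndarray) -> bool:
    a, b, c = np.asarray(pts, dtype=float)
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1e-30)
    u, v = b - a, c - a
    return abs(u[0] * v[1] - u[1] * v[0]) < 1e-12 * scale**2


@dataclass
class SliceRecord:
    """One slice: image reference, curves, marks and physical metadata."""

    index: int  # rostro-caudal order
    image_path: str
    pixel_size_um: float
    curves: dict = field(default_factory=dict)  # layer name -> PointSequence
    circle_points: np.ndarray | None = None  # (3, 2) needle-hole perimeter
    axis_mark: np.ndarray | None = None  # (2,)
    landmarks: dict = field(default_factory=dict)  # name -> (2,)
    loops: dict = field(default_factory=dict)  # name -> (k, 2) closed polygon

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError(f"slice {self.index}: pixel size must be positive")
        if self.circle_points is not None:
            cp = np.asarray(self.circle_points, dtype=float)
            if cp.shape != (3, 2):
                raise ValidationError(f"slice {self.index}: circle marks must be 3 points")
            if _collinear(cp):
                raise ValidationError(
                    f"slice {self.index}: circle-mark points are collinear"
                )


@dataclass
class Project:
    """Ordered slice stack plus acquisition metadata."""

    slices: list
    thickness_um: float = DEFAULT_THICKNESS_UM
    bin_count: int = DEFAULT_BIN_COUNT
    depth_windows: dict = field(default_factory=dict)  # layer -> (d0_um, d1_um)
    tissue_side: int = 1  # which side of the curves the tissue lies on
    metadata: dict = field(default_factory=dict)  # species, age, ...
    path: str | None = None  # set by read_project

    def validate(self, for_reconstruction: bool = False) -> None:
        if not self.slices:
            raise ValidationError("project has no slices")
        if self.thickness_um <= 0:
            raise ValidationError("slice thickness must be positive")
        idx = [s.index for s in self.slices]
        if any(b <= a for a, b in zip(idx[:-1], idx[1:])):
            raise ValidationError(f"slice indices not strictly increasing: {idx}")
        for s in self.slices:
            s.validate()
        if for_reconstruction:
            if len(self.slices) < 2:
                raise ValidationError("reconstruction needs at least 2 slices")
            if self.slices[0].axis_mark is None or self.slices[-1].axis_mark is None:
                raise ValidationError(
                    "axis marks are required on the first and last slices"
                )

    def resolve_image(self, record: SliceRecord) -> str:
        """Absolute image path, resolved relative to the project file."""
        p = record.image_path
        if os.path.isabs(p) or self.path is None:
            return p
        return os.path.join(os.path.dirname(os.path.abspath(self.path)), p)


# ---------------------------------------------------------------------------
# HDF5 container


def write_project(project: Project, path) -> None:
    """Write a validated project to an HDF5 container (versioned schema)."""
    project.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["thickness_um"] = float(project.thickness_um)
        f.attrs["bin_count"] = int(project.bin_count)
        f.attrs["tissue_side"] = int(project.tissue_side)
        f.attrs["metadata"] = json.dumps(project.metadata, sort_keys=True)
        dw = f.create_group("depth_windows")
        for layer, (d0, d1) in project.depth_windows.items():
            dw.create_dataset(layer, data=np.array([d0, d1], dtype=float))
        root = f.create_group("slices")
        for s in project.slices:
            g = root.create_group(f"{s.index:05d}")
            g.attrs["index"] = int(s.index)
            g.attrs["image_path"] = s.image_path
            g.attrs["pixel_size_um"] = float(s.pixel_size_um)
            cg = g.create_group("curves")
            for layer, seq in s.curves.items():
                lg = cg.create_group(layer)
                lg.create_dataset("points", data=seq.points)
                lg.create_dataset("boundaries", data=seq.boundaries)
            if s.circle_points is not None:
                g.create_dataset("circle_points", data=np.asarray(s.circle_points, float))
            if s.axis_mark is not None:
                g.create_dataset("axis_mark", data=np.asarray(s.axis_mark, float))
            lm = g.create_group("landmarks")
            for name, pt in s.landmarks.items():
                lm.create_dataset(name, data=np.asarray(pt, float))
            lp = g.create_group("loops")
            for name, poly in s.loops.items():
                lp.create_dataset(name, data=np.asarray(poly, float))


def read_project(path) -> Project:
    """Read and fully validate a project file."""
    if not os.path.exists(path):
        raise InvalidInputError(f"no such project file: {path}")
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version > SCHEMA_VERSION:
            raise ValidationError(f"unsupported schema version {version}")
        depth_windows = {
            k: tuple(np.asarray(v)) for k, v in f["depth_windows"].items()
        }
        slices = []
        for key in sorted(f["slices"].keys()):
            g = f["slices"][key]
            curves = {}
            for layer, lg in g["curves"].items():
                curves[layer] = PointSequence(
                    np.asarray(lg["points"]), np.asarray(lg["boundaries"])
                )
            slices.append(
                SliceRecord(
                    index=int(g.attrs["index"]),
                    image_path=str(g.attrs["image_path"]),
                    pixel_size_um=float(g.attrs["pixel_size_um"]),
                    curves=curves,
                    circle_points=np.asarray(g["circle_points"])
                    if "circle_points" in g else None,
                    axis_mark=np.asarray(g["axis_mark"]) if "axis_mark" in g else None,
                    landmarks={k: np.asarray(v) for k, v in g["landmarks"].items()},
                    loops={k: np.asarray(v) for k, v in g["loops"].items()},
                )
            )
        project = Project(
            slices=slices,
            thickness_um=float(f.attrs["thickness_um"]),
            bin_count=int(f.attrs["bin_count"]),
            depth_windows=depth_windows,
            tissue_side=int(f.attrs["tissue_side"]),
            metadata=json.loads(f.attrs["metadata"]),
            path=str(path),
        )
    project.validate()
    return project


# ---------------------------------------------------------------------------
# freehand-loop areas


def trace_area(loop: np.ndarray, scale: float = 1.0) -> float:
    """Absolute shoelace area of a simple closed polygon.

    ``scale`` converts vertex units to the reporting unit (e.g. px -> mm);
    the returned area is in (unit * scale)^2. Orientation-independent.
    """
    loop = np.asarray(loop, dtype=float)
    if loop.ndim != 2 or loop.shape[1] != 2 or len(loop) < 3:
        raise InvalidInputError("loop must be a polygon of >= 3 vertices")
    if not Polygon(loop).is_valid:
        raise InvalidInputError("loop polygon is self-intersecting")
    x, y = loop[:, 0], loop[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area * scale**2)


def region_fraction(loop: np.ndarray, cortex_outline: np.ndarray) -> float:
    """Loop area as a percentage of the cortical outline area (same frame)."""
    a_loop = trace_area(loop)
    a_cortex = trace_area(cortex_outline)
    if a_cortex <= 0:
        raise InvalidInputError("cortex outline has zero area")
    return 100.0 * a_loop / a_cortex
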