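"""Synthetic phantom brains with full analytic ground truth.

A phantom emulates a serial-section ISH experiment on a parametric hemisphere:
a half-cylinder (or half-ellipsoid) "cortex" whose surface carries a painted
expression pattern. Each coronal slice is rendered as a dark tissue rim on a
bright background — sub-surface darkness encodes the pattern sampled at that
slice's angular coordinate, matching dark-on-light ISH polarity — with a
stamped circular needle hole, a random rigid per-slice misalignment, and
optional pixel noise. Alongside the images, the generator emits everything a
real user would annotate (rim curve points, three circle-mark points, axis
marks, three reference landmarks) plus a :class:`PhantomTruth` holding the
analytic pattern, the true per-slice transforms and the true map coordinates
of every painted feature. Every ground-truth quantity is computed analytically,
never by running the pipeline; everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import imageio.v3 as iio
import numpy as np

from .curves import PointSequence
from .errors import InvalidInputError
from .mapmath import GridMap
from .project import Project, SliceRecord, write_project

__all__ = [
    "PatternElement",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomResult",
    "make_phantom",
    "truth_flatmap",
]


@dataclass
class PatternElement:
    """One painted surface feature, in surface coordinates (theta, x).

    kind: 'stripe' (Gaussian ridge at fixed angle, all x), 'blob' (isotropic
    Gaussian in surface-metric coordinates) or 'disc' (hard-edged disc, whose
    analytic area pi*width_mm**2 grounds region-fraction checks).
    width_mm is the Gaussian sigma (stripe/blob) or the disc radius.
    """

    kind: str
    theta: float
    x_mm: float = 0.0
    width_mm: float = 0.5
    amplitude: float = 1.0


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic brain.

    Defaults mirror the acquisition scale of the real experiments: 40 coronal
    slices cut at 100 µm, imaged at 20 µm/px, sampled at 150 bins per curve.
    """

    surface: str = "half-cylinder"  # or "half-ellipsoid"
    radius_mm: float = 2.0  # cylinder radius / ellipsoid max semi-axis
    axis_semi_mm: float | None = None  # ellipsoid rostro-caudal semi-axis
    n_slices: int = 40
    thickness_um: float = 100.0
    pixel_size_um: float = 20.0
    n_bins: int = 150
    theta_min: float = 0.0
    theta_max: float = np.pi
    zero_angle: float = np.pi / 2  # unwrapping angle phi (apex)
    pattern: list = field(default_factory=list)
    max_rotation_deg: float = 0.0
    max_jitter_px: float = 0.0
    noise_sd: float = 0.0
    hole_offset_mm: float = 1.2  # hole center below the dome center
    hole_radius_mm: float = 0.4  # 21-gauge needle scale
    rim_depth_um: float = 300.0  # painted band thickness below the surface
    background: float = 0.9
    signal_depth: float = 0.6  # max luminance drop at pattern amplitude 1
    margin_px: int = 72
    n_curve_points: int = 31  # rim points -> ten cubic groups over the dome

    def validate(self) -> None:
        if self.surface not in ("half-cylinder", "half-ellipsoid"):
            raise InvalidInputError(f"unknown surface family {self.surface!r}")
        for name in ("radius_mm", "thickness_um", "pixel_size_um", "hole_radius_mm",
                     "rim_depth_um", "signal_depth"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.n_slices < 2 or self.n_bins < 1:
            raise InvalidInputError("need >= 2 slices and >= 1 bin")
        if not self.theta_min < self.theta_max:
            raise InvalidInputError("need theta_min < theta_max")
        span_lo = self.theta_min - 0.05
        span_hi = self.theta_max + 0.05
        x_max = (self.n_slices - 1) * self.thickness_um / 1000.0
        for el in self.pattern:
            if not span_lo <= el.theta <= span_hi:
                raise InvalidInputError(
                    f"pattern element at theta={el.theta:.3f} lies off the surface"
                )
            if el.kind != "stripe" and not -0.05 <= el.x_mm <= x_max + 0.05:
                raise InvalidInputError(
                    f"pattern element at x={el.x_mm:.3f} mm lies off the surface"
                )


class _SurfaceGeom:
    """Per-slice cross-section geometry and arc-length coordinates."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.x_mm = np.arange(spec.n_slices) * spec.thickness_um / 1000.0
        if spec.surface == "half-ellipsoid":
            half = 0.5 * (self.x_mm[-1] - self.x_mm[0])
            self.x_center = 0.5 * (self.x_mm[0] + self.x_mm[-1])
            self.axis_semi = spec.axis_semi_mm if spec.axis_semi_mm else half / 0.8
            if self.axis_semi <= half:
                raise InvalidInputError("axis_semi_mm too short: end slices vanish")
        else:
            self.x_center = 0.0
            self.axis_semi = np.inf

    def semi_axes(self, x_mm: float) -> tuple[float, float]:
        """In-plane (horizontal, vertical) semi-axes at slice position x."""
        r = self.spec.radius_mm
        if self.spec.surface == "half-cylinder":
            return r, r
        f = np.sqrt(max(1e-9, 1.0 - ((x_mm - self.x_center) / self.axis_semi) ** 2))
        return r * f, r * f

    def _arc_table(self, x_mm: float):
        a, b = self.semi_axes(x_mm)
        al = np.linspace(self.spec.theta_min, self.spec.theta_max, 4001)
        speed = np.hypot(a * np.sin(al), b * np.cos(al))
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1])
                                               * np.diff(al))])
        cum -= np.interp(self.spec.zero_angle, al, cum)
        return al, cum

    def arc_u(self, alpha, x_mm: float):
        """Signed arc length (mm) from the zero angle to alpha, at slice x."""
        if self.spec.surface == "half-cylinder":
            return self.spec.radius_mm * (np.asarray(alpha) - self.spec.zero_angle)
        al, cum = self._arc_table(x_mm)
        return np.interp(alpha, al, cum)

    def u_range(self, x_mm: float) -> tuple[float, float]:
        lo = self.arc_u(self.spec.theta_min, x_mm)
        hi = self.arc_u(self.spec.theta_max, x_mm)
        return float(lo), float(hi)

    def pattern_value(self, u, x_mm):
        """Painted pattern at surface-metric coordinates (u, x), in [0, 1]."""
        u = np.asarray(u, dtype=float)
        x = np.broadcast_to(np.asarray(x_mm, dtype=float), u.shape)
        out = np.zeros_like(u)
        for el in self.spec.pattern:
            if el.kind == "stripe":
                uc = self.arc_u(el.theta, 0.0 if np.ndim(x_mm) == 0 else float(np.mean(x)))
                out += el.amplitude * np.exp(-0.5 * ((u - uc) / el.width_mm) ** 2)
            elif el.kind == "blob":
                uc = self.arc_u(el.theta, el.x_mm)
                d2 = (u - uc) ** 2 + (x - el.x_mm) ** 2
                out += el.amplitude * np.exp(-0.5 * d2 / el.width_mm**2)
            elif el.kind == "disc":
                uc = self.arc_u(el.theta, el.x_mm)
                d2 = (u - uc) ** 2 + (x - el.x_mm) ** 2
                out += el.amplitude * (d2 <= el.width_mm**2)
            else:
                raise InvalidInputError(f"unknown pattern kind {el.kind!r}")
        return np.clip(out, 0.0, 1.0)


@dataclass
class PhantomTruth:
    """Analytic ground truth for one generated phantom."""

    spec: PhantomSpec
    geom: _SurfaceGeom
    rotations_rad: np.ndarray  # (M,) true misalignment rotation per slice
    jitters_px: np.ndarray  # (M, 2) true misalignment translation per slice
    hole_center_px: np.ndarray  # (2,) aligned hole center (rotation center)
    dome_center_px: np.ndarray  # (2,) aligned dome center (on the brain axis)
    landmark_uv: dict  # name -> (u, v) mm in the unwrapped frame

    @property
    def slice_x_mm(self) -> np.ndarray:
        return self.geom.x_mm

    def stripe_u_mm(self, element: PatternElement) -> float:
        """Expected map position of a stripe: u = r * (theta_s - phi)."""
        return float(self.geom.arc_u(element.theta, 0.0))

    def flat_width_mm(self, x_mm: float) -> float:
        lo, hi = self.geom.u_range(x_mm)
        return hi - lo

    def outline_area_mm2(self) -> float:
        """Analytic area of the unwrapped map (between first and last slices)."""
        widths = np.array([self.flat_width_mm(x) for x in self.geom.x_mm])
        mid = 0.5 * (widths[1:] + widths[:-1])
        return float(np.sum(mid * np.diff(self.geom.x_mm)))

    def disc_area_mm2(self, element: PatternElement) -> float:
        if element.kind != "disc":
            raise InvalidInputError("analytic area is defined for disc elements")
        return float(np.pi * element.width_mm**2)

    def region_fraction_pct(self, element: PatternElement) -> float:
        return 100.0 * self.disc_area_mm2(element) / self.outline_area_mm2()

    def to_json(self) -> str:
        d = {
            "spec": {**asdict(self.spec), "pattern": [asdict(e) for e in self.spec.pattern]},
            "rotations_rad": self.rotations_rad.tolist(),
            "jitters_px": self.jitters_px.tolist(),
            "hole_center_px": self.hole_center_px.tolist(),
            "dome_center_px": self.dome_center_px.tolist(),
            "landmark_uv": {k: list(map(float, v)) for k, v in self.landmark_uv.items()},
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PhantomResult:
    project: Project
    truth: PhantomTruth
    images: list  # per-slice (H, W) float rasters in [0, 1]


def _layout(spec: PhantomSpec) -> dict:
    px_mm = spec.pixel_size_um / 1000.0
    r_px = spec.radius_mm / px_mm
    hole_off_px = spec.hole_offset_mm / px_mm
    hole_r_px = spec.hole_radius_mm / px_mm
    W = int(np.ceil(2 * r_px + 2 * spec.margin_px))
    cy = spec.margin_px + r_px
    H = int(np.ceil(cy + hole_off_px + hole_r_px + spec.margin_px))
    return {
        "px_mm": px_mm,
        "W": W,
        "H": H,
        "center": np.array([W / 2.0, cy]),
        "hole_center": np.array([W / 2.0, cy + hole_off_px]),
        "hole_r_px": hole_r_px,
    }


def _render_slice(spec: PhantomSpec, geom: _SurfaceGeom, lay: dict, i: int,
                  rot: float, jit: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    H, W = lay["H"], lay["W"]
    px_mm = lay["px_mm"]
    c = lay["center"]
    h = lay["hole_center"]
    x_mm = geom.x_mm[i]
    a, b = geom.semi_axes(x_mm)

    xs, ys = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    # undo the misalignment: image px -> aligned px
    co, si = np.cos(-rot), np.sin(-rot)
    dx = xs - jit[0] - h[0]
    dy = ys - jit[1] - h[1]
    ax = co * dx - si * dy + h[0]
    ay = si * dx + co * dy + h[1]

    # normalized elliptical coordinates about the dome center (y-up angles)
    qy = (ax - c[0]) * px_mm / a
    qz = (c[1] - ay) * px_mm / b
    rho = np.hypot(qy, qz)
    alpha = np.arctan2(qz, qy)

    img = np.full((H, W), spec.background)
    radius_at = np.hypot(a * np.cos(alpha), b * np.sin(alpha))
    depth_mm = (1.0 - rho) * radius_at  # approx. inward distance to the rim
    band = (
        (depth_mm >= 0.0)
        & (depth_mm <= spec.rim_depth_um / 1000.0)
        & (alpha >= spec.theta_min)
        & (alpha <= spec.theta_max)
    )
    if band.any():
        u = geom.arc_u(alpha[band], x_mm)
        img[band] = spec.background - spec.signal_depth * geom.pattern_value(u, x_mm)

    # needle hole: bright interior, thin dark rim
    dh = np.hypot(ax - h[0], ay - h[1])
    img[np.abs(dh - lay["hole_r_px"]) < 1.5] = 0.3
    img[dh < lay["hole_r_px"] - 1.5] = 1.0

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    # quantize exactly as written to disk, so in-memory and file runs agree
    return np.round(img * 65535.0) / 65535.0


_LANDMARK_PLACEMENT = {
    "lm1": (2, 0.75 * np.pi),
    "lm2": (-3, 0.70 * np.pi),
    "lm3": (None, 0.25 * np.pi),  # None -> middle slice
}


def make_phantom(spec: PhantomSpec, seed: int, out_dir=None) -> PhantomResult:
    """Generate a phantom: slice images, annotated project and ground truth.

    Deterministic given (spec, seed). If ``out_dir`` is given, slice images
    (16-bit PNG), the project container (HDF5) and the truth (JSON) are
    written there as well.
    """
    spec.validate()
    geom = _SurfaceGeom(spec)
    lay = _layout(spec)
    M = spec.n_slices
    rng = np.random.default_rng(seed)
    rotations = rng.uniform(-1.0, 1.0, M) * np.deg2rad(spec.max_rotation_deg)
    jitters = rng.uniform(-1.0, 1.0, (M, 2)) * spec.max_jitter_px
    rotations[0] = 0.0  # slice 0 anchors the stack
    jitters[0] = 0.0

    h = lay["hole_center"]
    c = lay["center"]
    px_mm = lay["px_mm"]

    def misalign(pts: np.ndarray, i: int) -> np.ndarray:
        co, si = np.cos(rotations[i]), np.sin(rotations[i])
        R = np.array([[co, -si], [si, co]])
        return (np.atleast_2d(pts) - h) @ R.T + h + jitters[i]

    images = []
    slices = []
    layer = "L4"
    mark_angles = np.deg2rad([15.0, 135.0, 255.0])
    for i in range(M):
        images.append(_render_slice(spec, geom, lay, i, rotations[i], jitters[i], rng))
        a, b = geom.semi_axes(geom.x_mm[i])
        al = np.linspace(spec.theta_min, spec.theta_max, spec.n_curve_points)
        rim = np.column_stack([
            c[0] + (a / px_mm) * np.cos(al),
            c[1] - (b / px_mm) * np.sin(al),
        ])
        curve_pts = misalign(rim, i)
        circle = misalign(
            h + lay["hole_r_px"] * np.column_stack([np.cos(mark_angles),
                                                    np.sin(mark_angles)]), i)
        rec = SliceRecord(
            index=i,
            image_path=f"slice_{i:04d}.png",
            pixel_size_um=spec.pixel_size_um,
            curves={layer: PointSequence.from_points(curve_pts, max_group=4)},
            circle_points=circle,
            axis_mark=misalign(c, i)[0] if i in (0, M - 1) else None,
        )
        slices.append(rec)

    landmark_uv = {}
    for name, (si, theta) in _LANDMARK_PLACEMENT.items():
        i = M // 2 if si is None else (si if si >= 0 else M + si)
        i = min(max(i, 0), M - 1)
        a, b = geom.semi_axes(geom.x_mm[i])
        pt = np.array([c[0] + (a / px_mm) * np.cos(theta),
                       c[1] - (b / px_mm) * np.sin(theta)])
        slices[i].landmarks[name] = misalign(pt, i)[0]
        landmark_uv[name] = (float(geom.arc_u(theta, geom.x_mm[i])),
                             float(geom.x_mm[i]))

    project = Project(
        slices=slices,
        thickness_um=spec.thickness_um,
        bin_count=spec.n_bins,
        depth_windows={layer: (0.0, 0.8 * spec.rim_depth_um)},
        tissue_side=-1,  # rim traversed lateral->medial; tissue lies inward
        metadata={"phantom": True, "surface": spec.surface, "seed": int(seed)},
    )
    truth = PhantomTruth(
        spec=spec,
        geom=geom,
        rotations_rad=rotations,
        jitters_px=jitters,
        hole_center_px=h.copy(),
        dome_center_px=c.copy(),
        landmark_uv=landmark_uv,
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i, img in enumerate(images):
            iio.imwrite(os.path.join(out_dir, f"slice_{i:04d}.png"),
                        np.round(img * 65535.0).astype(np.uint16))
        write_project(project, os.path.join(out_dir, "project.h5"))
        project.path = os.path.join(out_dir, "project.h5")
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())
    return PhantomResult(project=project, truth=truth, images=images)


def noise_sd_for_box_snr(spec: PhantomSpec, snr: float) -> float:
    """Pixel-noise SD giving a target signal-to-noise ratio at the box level.

    SNR is defined on box means: the SD of the rendered pattern amplitude
    across sampling bins divided by the pixel noise attenuated by averaging
    over one box's pixels. Everything is computed analytically from the spec
    (pattern evaluated at bin centers, box pixel count from the geometry);
    the pipeline is never consulted.
    """
    spec.validate()
    geom = _SurfaceGeom(spec)
    vals = []
    for x in geom.x_mm:
        lo, hi = geom.u_range(x)
        edges = np.linspace(lo, hi, spec.n_bins + 1)
        vals.append(geom.pattern_value(0.5 * (edges[1:] + edges[:-1]), x))
    sd_pattern = float(np.std(np.concatenate(vals)))
    if sd_pattern == 0.0:
        raise InvalidInputError("pattern has no variance; SNR is undefined")
    px_mm = spec.pixel_size_um / 1000.0
    band_px = 0.8 * spec.rim_depth_um / spec.pixel_size_um
    widths = [geom.u_range(x)[1] - geom.u_range(x)[0] for x in geom.x_mm]
    arc_px = float(np.mean(widths)) / spec.n_bins / px_mm
    n_box_pixels = band_px * arc_px
    return spec.signal_depth * sd_pattern * np.sqrt(n_box_pixels) / snr


def truth_flatmap(truth: PhantomTruth, pixel_mm: float, origin, shape) -> GridMap:
    """Ground-truth pattern evaluated directly on a grid geometry.

    No imaging, alignment or unwrapping is involved: for each grid pixel
    center (u, v) on the surface's unwrapped footprint the analytic pattern is
    evaluated in surface-metric coordinates. Used as the independent reference
    for end-to-end correlation checks.
    """
    origin = np.asarray(origin, dtype=float)
    H, W = shape
    us = origin[0] + pixel_mm * np.arange(W)
    vs = origin[1] + pixel_mm * np.arange(H)
    values = np.full((H, W), np.nan)
    mask = np.zeros((H, W), dtype=bool)
    x_lo, x_hi = truth.slice_x_mm[0], truth.slice_x_mm[-1]
    for row, v in enumerate(vs):
        if not x_lo <= v <= x_hi:
            continue
        lo, hi = truth.geom.u_range(v)
        ok = (us >= lo) & (us <= hi)
        if not ok.any():
            continue
        values[row, ok] = truth.geom.pattern_value(us[ok], v)
        mask[row, ok] = True
    return GridMap(values, mask, float(pixel_mm), origin)
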