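"""End-to-end reconstruction pipeline: project + images -> flat maps.

Glue over the stage modules, in the order a user runs them:

1. fit piecewise Bézier curves per slice and layer, lay N+1 equally spaced
   sample frames, build sampling boxes over each layer's depth window;
2. illumination-correct each slice image and take box means; rescale the box
   means per brain (robust 1st-99th percentile);
3. estimate hole centers from circle marks, align the stack (translation to
   the alignment axis + sequential rotation optimization), apply the
   transforms to all sampled coordinates;
4. lift ribbons into 3D, locate zero marks at the unwrapping angle, unwrap
   each layer into a flat map, and carry named landmarks into map coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alignment, curves, flatten, imaging
from .errors import InvalidInputError
from .project import Project

__all__ = ["Reconstruction", "reconstruct", "flatten_layer", "run_pipeline"]


@dataclass
class Reconstruction:
    """Aligned per-layer surfaces plus the transforms that produced them."""

    project: Project
    transforms: list  # per-slice SliceTransform
    surfaces: dict  # layer -> Surface3D
    frames: dict  # layer -> list of CurveFrames (pre-alignment, px)
    landmarks: dict = field(default_factory=dict)  # name -> (slice index, aligned px)


def _load_images(project: Project, images=None) -> list:
    if images is not None:
        if len(images) != len(project.slices):
            raise InvalidInputError("need one image per slice")
        return [np.asarray(im, dtype=float) for im in images]
    return [
        imaging.load_image(project.resolve_image(rec), rec.pixel_size_um).raster
        for rec in project.slices
    ]


def reconstruct(project: Project, images=None, blur_sigma_px: float | None = None,
                normalize: bool = True) -> Reconstruction:
    """Run stages 1-4 for every layer of a project.

    ``images`` may supply in-memory rasters (one per slice, luminance in
    [0, 1]); otherwise images are loaded from the slice records' paths.
    """
    project.validate(for_reconstruction=True)
    rasters = _load_images(project, images)
    layers = list(project.slices[0].curves.keys())
    if not layers:
        raise InvalidInputError("slice 0 has no curves")
    N = project.bin_count
    px_sizes = {rec.pixel_size_um for rec in project.slices}
    if len(px_sizes) != 1:
        raise InvalidInputError("mixed pixel sizes are not supported")
    px_um = px_sizes.pop()

    # stage 1-2: frames, boxes, illumination-corrected box means
    frames: dict = {layer: [] for layer in layers}
    values: dict = {layer: [] for layer in layers}
    for rec, raster in zip(project.slices, rasters):
        img = imaging.LuminanceImage(raster, rec.pixel_size_um)
        signal = imaging.background_subtract(img, blur_sigma_px)
        for layer in layers:
            if layer not in rec.curves:
                raise InvalidInputError(f"slice {rec.index} lacks layer {layer!r}")
            curve = curves.fit_piecewise(rec.curves[layer])
            fr = curves.sample_frames(curve, N, project.tissue_side)
            d0, d1 = project.depth_windows.get(layer, (0.0, 300.0))
            boxes = curves.make_sample_boxes(fr, d0, d1, rec.pixel_size_um)
            frames[layer].append(fr)
            values[layer].append(imaging.sample_boxes(signal, boxes))
    vals = {layer: np.asarray(v) for layer, v in values.items()}
    if normalize:
        flat = np.concatenate([v.ravel() for v in vals.values()])
        normed = imaging.normalize_values(flat)
        pos = 0
        for layer in layers:
            n = vals[layer].size
            vals[layer] = normed[pos:pos + n].reshape(vals[layer].shape)
            pos += n

    # stage 3: align on all layers' frame points concatenated
    stack_pts = [
        np.concatenate([frames[layer][i].points for layer in layers])
        for i in range(len(project.slices))
    ]
    if all(rec.circle_points is not None for rec in project.slices):
        centers = [alignment.circumcircle(*rec.circle_points).center
                   for rec in project.slices]
    else:
        centers = None
    transforms = alignment.align_stack(stack_pts, centers)

    # stage 4: surfaces per layer
    x_um = np.array([rec.index for rec in project.slices]) * project.thickness_um
    first, last = project.slices[0], project.slices[-1]
    axis_marks = (
        transforms[0].apply(np.asarray(first.axis_mark, dtype=float)),
        transforms[-1].apply(np.asarray(last.axis_mark, dtype=float)),
    )
    surfaces = {}
    for layer in layers:
        aligned = [tr.apply(fr.points) for tr, fr in zip(transforms, frames[layer])]
        surfaces[layer] = flatten.build_surface(
            aligned, vals[layer], axis_marks, x_um, px_um
        )

    landmarks = {}
    for i, rec in enumerate(project.slices):
        for name, pt in rec.landmarks.items():
            landmarks[name] = (i, transforms[i].apply(np.asarray(pt, dtype=float)))
    return Reconstruction(project, transforms, surfaces, frames, landmarks)


def flatten_layer(recon: Reconstruction, layer: str,
                  phi: float = np.pi / 2) -> flatten.FlatMap:
    """Unwrap one layer's surface about the angle ``phi`` into a flat map."""
    if layer not in recon.surfaces:
        raise InvalidInputError(f"no such layer {layer!r}")
    surface = recon.surfaces[layer]
    zeros = flatten.find_zero_marks(surface, phi)
    fm = flatten.unwrap(surface, zeros)
    px_um = recon.project.slices[0].pixel_size_um
    for name, (i, pt) in recon.landmarks.items():
        fm.landmarks[name] = flatten.project_point_to_map(surface, fm, i, pt, px_um)
    return fm


def run_pipeline(project: Project, images=None, layer: str | None = None,
                 phi: float = np.pi / 2,
                 blur_sigma_px: float | None = None) -> flatten.FlatMap:
    """One-call convenience: reconstruct and unwrap a single layer."""
    recon = reconstruct(project, images, blur_sigma_px)
    if layer is None:
        layer = list(recon.surfaces.keys())[0]
    return flatten_layer(recon, layer, phi)
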