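"""Slice-image loading, illumination correction and sampling-box quantification.

ISH signal is dark-on-light: high mRNA expression shows as low luminance. To
remove slowly varying illumination differences between slices imaged at
different orientations, each image is blurred with a very wide Gaussian kernel
and the result compared with the original; the (clamped) difference
``max(0, blur - original)`` is the expression signal, so higher values mean
more expression.

Box means are taken over all pixel centers strictly inside each quadrilateral
sampling box; per-brain values are made comparable across slices by a robust
1st-99th percentile rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .errors import (
    DegenerateNormalizationError,
    InvalidInputError,
)

__all__ = [
    "LuminanceImage",
    "SignalImage",
    "load_image",
    "to_luminance",
    "background_subtract",
    "sample_box_mean",
    "sample_boxes",
    "normalize_values",
]

# Rec. 601 luma weights, fixed for deterministic RGB conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class LuminanceImage:
    """Grayscale raster with luminance in [0, 1] and physical pixel size."""

    raster: np.ndarray  # (H, W) float64 in [0, 1]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.raster = np.clip(np.asarray(self.raster, dtype=float), 0.0, 1.0)
        if self.raster.ndim != 2:
            raise InvalidInputError("luminance raster must be 2D")
        if self.pixel_size_um <= 0:
            raise InvalidInputError("pixel size must be positive")


@dataclass
class SignalImage:
    """Nonnegative expression signal derived from a luminance image."""

    raster: np.ndarray  # (H, W) float64, >= 0
    pixel_size_um: float
    blur_sigma_px: float


def to_luminance(raw: np.ndarray, pixel_size_um: float) -> LuminanceImage:
    """Convert a raw decoded array (8/16-bit, gray/RGB/RGBA) to luminance."""
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return LuminanceImage(arr, pixel_size_um)


def load_image(path, pixel_size_um: float) -> LuminanceImage:
    """Read a TIFF/PNG/JPEG slice image from disk."""
    return to_luminance(iio.imread(path), pixel_size_um)


def background_subtract(img: LuminanceImage, sigma_px: float | None = None) -> SignalImage:
    """Wide-Gaussian illumination correction leaving the (dark) signal.

    ``signal = max(0, blur(img, sigma) - img)``: the blurred image estimates
    local illumination, and because expression stains dark, the original dips
    below it where expression is high. Default sigma is 10% of the image
    width; image borders are handled by edge replication.
    """
    if sigma_px is None:
        sigma_px = 0.1 * img.raster.shape[1]
    if sigma_px <= 0:
        raise InvalidInputError("blur sigma must be positive")
    blur = gaussian_filter(img.raster, sigma=sigma_px, mode="nearest")
    signal = np.maximum(0.0, blur - img.raster)
    return SignalImage(signal, img.pixel_size_um, float(sigma_px))


def _box_polygon(box: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(box, dtype=float))
    if (not poly.is_valid) or poly.area <= 0.0:
        raise InvalidInputError("sampling box is degenerate or self-intersecting")
    return poly


def sample_box_mean(signal: SignalImage | np.ndarray, box: np.ndarray) -> float:
    """Mean signal over pixel centers strictly inside a quadrilateral box.

    Pixel centers sit at integer (x=column, y=row) coordinates. Returns NaN if
    no pixel center falls inside the box (e.g. a box off the image edge).
    """
    raster = signal.raster if isinstance(signal, SignalImage) else np.asarray(signal)
    poly = _box_polygon(box)
    h, w = raster.shape
    x0, y0, x1, y1 = poly.bounds
    cx0, cx1 = max(0, int(np.ceil(x0))), min(w - 1, int(np.floor(x1)))
    cy0, cy1 = max(0, int(np.ceil(y0))), min(h - 1, int(np.floor(y1)))
    if cx0 > cx1 or cy0 > cy1:
        return float("nan")
    xs, ys = np.meshgrid(np.arange(cx0, cx1 + 1), np.arange(cy0, cy1 + 1))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
    if not inside.any():
        return float("nan")
    return float(raster[ys.ravel()[inside], xs.ravel()[inside]].mean())


def sample_boxes(signal: SignalImage | np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Vector of box means for an (N, 4, 2) stack of boxes."""
    return np.array([sample_box_mean(signal, b) for b in boxes])


def normalize_values(values: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Per-brain robust rescale of box means to [0, 1].

    ``(v - P_lo) / (P_hi - P_lo)`` clamped to [0, 1], with percentiles taken
    over all finite box means of the brain; NaNs (missing boxes) pass through.
    Invariant under positive affine rescaling of the raw values.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise InvalidInputError("no finite values to normalize")
    lo, hi = np.percentile(values[finite], [p_lo, p_hi])
    if hi <= lo:
        raise DegenerateNormalizationError("constant data: percentile range is zero")
    out = np.full_like(values, np.nan)
    out[finite] = np.clip((values[finite] - lo) / (hi - lo), 0.0, 1.0)
    return out
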