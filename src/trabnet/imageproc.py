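"""Slice preprocessing: read, contrast-adjust, ROI segmentation, binarization,
cleaning, and thinning of trabecular micro-CT slices.

The pipeline mirrors the classical vascular/trabecular extraction recipe:
grayscale normalization to [0, 1], optional percentile contrast stretch,
optional region-of-interest masking, global (Otsu) or manual thresholding,
speckle/hole cleaning, and topology-preserving thinning to a one-pixel-wide
skeleton. Foreground uses 8-connectivity, background holes 4-connectivity
(the standard duality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from skimage import draw as _draw
from skimage import filters, morphology
from skimage.color import rgb2gray

logger = logging.getLogger(__name__)

#: default slice spacing / in-plane pixel size of the reference scanner setup
DEFAULT_PIXEL_SIZE_UM = 20.5


@dataclass(frozen=True)
class SliceImage:
    """One grayscale micro-CT slice, values normalized to [0, 1].

    ``depth_mm`` is derived from ``depth_index`` assuming isotropic voxels
    (slice spacing equal to the in-plane pixel size).
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    depth_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {px.shape}")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValueError("pixel values must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def depth_mm(self) -> float:
        return self.depth_index * self.pixel_size_um / 1000.0


@dataclass(frozen=True)
class BinaryMask:
    """Boolean bone mask (True = bone) with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide medial-line skeleton of a bone mask."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"skeleton must be 2D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CircleROI:
    """Disc region of interest: ``center`` as (row, col), ``radius`` in px."""

    center: tuple[float, float]
    radius: float

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = self.center
        if not (0 <= r - self.radius and r + self.radius <= shape[0] - 1
                and 0 <= c - self.radius and c + self.radius <= shape[1] - 1):
            raise ValueError("circular ROI extends outside the image frame")
        rr, cc = _draw.disk(self.center, self.radius + 0.5, shape=shape)
        m = np.zeros(shape, bool)
        m[rr, cc] = True
        return m


@dataclass(frozen=True)
class PolygonROI:
    """Polygon region of interest; vertices as (row, col) pairs."""

    vertices: tuple[tuple[float, float], ...]

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        v = np.asarray(self.vertices, float)
        if (v[:, 0].min() < 0 or v[:, 0].max() > shape[0] - 1
                or v[:, 1].min() < 0 or v[:, 1].max() > shape[1] - 1):
            raise ValueError("polygon ROI extends outside the image frame")
        rr, cc = _draw.polygon(v[:, 0], v[:, 1], shape=shape)
        m = np.zeros(shape, bool)
        m[rr, cc] = True
        return m


def read_slice(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
               depth_index: int = 0) -> SliceImage:
    """Read a TIFF/PNG slice and rescale to [0, 1] by bit depth.

    RGB input is converted to grayscale with ITU-R luminance weights.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - delegated to imageio
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = rgb2gray(arr[..., :3].astype(float) / _bit_scale(arr.dtype))
    elif arr.ndim == 2:
        arr = arr.astype(float) / _bit_scale(arr.dtype)
    else:
        raise ValueError(f"unsupported image dimensionality {arr.shape} in {path!r}")
    return SliceImage(np.clip(arr, 0.0, 1.0), pixel_size_um, depth_index)


def _bit_scale(dtype) -> float:
    dt = np.dtype(dtype)
    if dt == np.uint8:
        return 255.0
    if dt == np.uint16:
        return 65535.0
    if dt.kind == "f":
        return 1.0
    raise ValueError(f"unsupported image dtype {dt}")


def adjust(img: SliceImage, low_pct: float = 1.0, high_pct: float = 99.0) -> SliceImage:
    """Linear contrast stretch mapping [low, high] percentiles to [0, 1]."""
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(img.pixels, [low_pct, high_pct])
    if hi <= lo:
        logger.warning("adjust: degenerate (constant) image, returned unchanged")
        return img
    stretched = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return replace(img, pixels=stretched)


def segment_roi(img: SliceImage, roi: CircleROI | PolygonROI | None = None) -> SliceImage:
    """Zero out everything outside the region of interest (identity if None)."""
    if roi is None:
        return img
    mask = roi.rasterize(img.shape)
    return replace(img, pixels=np.where(mask, img.pixels, 0.0))


def binarize(img: SliceImage, threshold: float | None = None) -> BinaryMask:
    """Threshold to a bone mask; Otsu's method when no threshold is given."""
    px = img.pixels
    if threshold is None:
        if np.ptp(px) == 0:
            logger.warning("binarize: constant image has no foreground")
            return BinaryMask(np.zeros(px.shape, bool), img.pixel_size_um)
        threshold = filters.threshold_otsu(px)
    return BinaryMask(px > threshold, img.pixel_size_um)


def clean(mask: BinaryMask, min_object_px: int = 20, min_hole_px: int = 20) -> BinaryMask:
    """Drop small 8-connected specks and fill small 4-connected holes."""
    if min_object_px < 0 or min_hole_px < 0:
        raise ValueError("size thresholds must be nonnegative")
    px = mask.pixels
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skimage warns on no-op thresholds
        if min_object_px > 0:
            px = morphology.remove_small_objects(px, min_size=min_object_px, connectivity=2)
        if min_hole_px > 0:
            px = morphology.remove_small_holes(px, area_threshold=min_hole_px, connectivity=1)
    return BinaryMask(px, mask.pixel_size_um)


def skeletonize(mask: BinaryMask) -> Skeleton:
    """Reduce the mask to one-pixel-wide medial lines.

    Uses iterative Zhang–Suen-class thinning, which preserves 8-connectivity
    topology and guarantees no 2x2 block of skeleton pixels remains.
    """
    return Skeleton(morphology.thin(mask.pixels), mask.pixel_size_um)
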