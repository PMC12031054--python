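"""Leaf segmentation and color extraction from RGB photographs.

Photographs are expected to show a single leaf on a bright, near-white
background (light-box acquisition).  The leaf is isolated by thresholding
in HSV space — hue and saturation are far less sensitive to illumination
than raw RGB, and a white paper background is characteristically
high-value / low-saturation — followed by largest-connected-component
selection and hole filling.  Channel means over the resulting region of
interest are the raw material for every downstream color index.

Images are plain ``uint8`` H×W×3 arrays in red-green-blue channel order;
masks are boolean H×W arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import ConfigError, EmptyROI, NoLeafFound

__all__ = [
    "SegmentationConfig",
    "LeafMask",
    "MeanChannelColor",
    "load_image",
    "rgb_to_hsv",
    "segment_leaf",
    "median_filter_roi",
    "mean_channels",
    "save_mask",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for HSV background removal.

    Parameters
    ----------
    s_min:
        Minimum saturation (0–1) for a pixel to count as leaf candidate.
        White paper sits near zero saturation.
    v_max:
        Maximum value (0–1); the bright background exceeds this.
    hue_range:
        Optional ``(lo, hi)`` gate in degrees.  Disabled by default:
        chlorotic leaves can drift below the green hue band, and the
        saturation/value gates already separate them from white paper.
    """

    s_min: float = 0.15
    v_max: float = 0.98
    hue_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_min <= 1.0:
            raise ConfigError(f"s_min must be in [0, 1], got {self.s_min}")
        if not 0.0 < self.v_max <= 1.0:
            raise ConfigError(f"v_max must be in (0, 1], got {self.v_max}")
        if self.hue_range is not None:
            lo, hi = self.hue_range
            if not (0 <= lo < hi <= 360):
                raise ConfigError(f"hue_range must satisfy 0 <= lo < hi <= 360, got {self.hue_range}")


@dataclass
class LeafMask:
    """Filled region of interest for one leaf.

    ``mask`` is boolean with the same H×W as the source image; ``contour``
    is the (row, col) boundary polyline of the retained component;
    ``area_px`` is the filled pixel count.
    """

    mask: np.ndarray
    contour: np.ndarray
    area_px: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.area_px)
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area_px does not match the mask")


@dataclass(frozen=True)
class MeanChannelColor:
    """Arithmetic channel means over the leaf region, 0–255 scale."""

    mean_R: float
    mean_G: float
    mean_B: float
    n_pixels: int


def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG as an H×W×3 uint8 RGB array.

    Grayscale images are broadcast to three channels; an alpha channel is
    dropped.  Unreadable files raise ``IOError`` naming the path.
    """
    path = Path(path)
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise decoder errors
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise IOError(f"cannot read image file {path}: unexpected shape {img.shape}")
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return np.ascontiguousarray(img, dtype=np.uint8)


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert uint8 RGB to HSV with hue in degrees [0, 360).

    Standard hexcone conversion; achromatic pixels get hue 0.  Saturation
    and value are in [0, 1].
    """
    from skimage.color import rgb2hsv

    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 image, got shape {arr.shape}")
    hsv = rgb2hsv(arr)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def segment_leaf(img: np.ndarray, cfg: SegmentationConfig | None = None) -> LeafMask:
    """Isolate the leaf as the filled largest connected foreground component.

    Foreground candidates are pixels with saturation >= ``cfg.s_min`` and
    value <= ``cfg.v_max`` (optionally hue-gated).  Connected components
    are labelled with 8-connectivity; the largest one is kept (ties broken
    by the component whose first pixel in row-major order comes first),
    and holes inside it are filled so that veins and specular spots stay
    part of the region of interest.
    """
    cfg = cfg or SegmentationConfig()
    hsv = rgb_to_hsv(img)
    fg = (hsv[..., 1] >= cfg.s_min) & (hsv[..., 2] <= cfg.v_max)
    if cfg.hue_range is not None:
        lo, hi = cfg.hue_range
        fg &= (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi)
    if not fg.any():
        raise NoLeafFound("no foreground pixel survived HSV thresholding")

    labels, n_labels = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) == 1:
        best = candidates[0]
    else:
        # tie-break: component containing the row-major-first pixel
        flat = labels.ravel()
        firsts = [np.argmax(flat == c) for c in candidates]
        best = candidates[int(np.argmin(firsts))]

    mask = ndi.binary_fill_holes(labels == best)
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    return LeafMask(mask=mask, contour=contour, area_px=int(mask.sum()))


def median_filter_roi(img: np.ndarray, mask: LeafMask, kernel: int = 5) -> np.ndarray:
    """Median-filter each channel, replacing only pixels inside the mask.

    ``kernel`` must be odd and positive.  Pixels outside the region of
    interest are returned unchanged, so the background keeps its original
    values and the leaf interior is denoised.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ConfigError(f"median filter kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return img.copy()
    out = img.copy()
    filtered = np.empty_like(img)
    for c in range(3):
        filtered[:, :, c] = ndi.median_filter(img[:, :, c], size=kernel, mode="nearest")
    out[mask.mask] = filtered[mask.mask]
    return out


def mean_channels(img: np.ndarray, mask: LeafMask) -> MeanChannelColor:
    """Per-channel arithmetic means over the masked leaf pixels."""
    if mask.area_px == 0:
        raise EmptyROI("mask contains no leaf pixel")
    pix = img[mask.mask].astype(np.float64)
    m = pix.mean(axis=0)
    return MeanChannelColor(mean_R=float(m[0]), mean_G=float(m[1]), mean_B=float(m[2]), n_pixels=mask.area_px)


def save_mask(mask: LeafMask, path: str | Path) -> None:
    """Write the mask as a single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))
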