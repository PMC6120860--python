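"""Loading and binarization of en-face OCT-A angiograms.

The device exports 8-bit en-face angiograms (bright flow signal on a dark
background). The quantification pipeline mirrors the standard ImageJ recipe
used in the OCT-A literature: split RGB exports into channels, keep the red
channel as reference, auto-threshold with the default iterative-intermeans
rule under the dark-background convention, and binarize. Vessel pixels are
the in-range pixels; everything else is background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)

SLABS = ("SCP", "DCP", "choriocapillaris")


@dataclass(frozen=True)
class Angiogram:
    """One en-face 8-bit angiogram plus its physical scale and slab label.

    ``processed`` marks images that have been thresholded or re-rendered;
    mean-gray-value analysis refuses those (it is defined on the raw export).
    """

    pixels: np.ndarray
    scale_mm_per_px: float
    slab: str
    source_path: str | None = None
    processed: bool = False

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 2:
            raise ValueError("Angiogram pixels must be a 2-D uint8 array")
        if not self.scale_mm_per_px > 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.slab not in SLABS:
            raise ValueError(f"slab must be one of {SLABS}, got {self.slab!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ThresholdBounds:
    """Inclusive gray-level window [lower, upper] defining vessel pixels."""

    lower: int
    upper: int = 255
    mode: str = "auto_default"

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper <= 255):
            raise ValueError("require 0 <= lower <= upper <= 255")


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster (True = vessel) on the same grid as its parent."""

    mask: np.ndarray
    scale_mm_per_px: float
    bounds_used: ThresholdBounds | None = None
    slab: str | None = None

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")

    @property
    def vessel_px(self) -> int:
        return int(self.mask.sum())


def extract_red_channel(img: np.ndarray) -> np.ndarray:
    """Return the red plane of an RGB(A) export, or pass grayscale through.

    The device export is split into channels and the red channel is kept as
    the reference plane. 16-bit or float inputs are rejected: convert to
    8-bit explicitly before calling.
    """
    if img.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit input, got dtype {img.dtype}; convert explicitly"
        )
    if img.ndim == 2:
        log.info("grayscale input: no channel split, passed through unchanged")
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return np.ascontiguousarray(img[:, :, 0])
    raise ValueError(f"expected 1- or 3-channel image, got shape {img.shape}")


def load_angiogram(path: str, slab: str, field_mm: float = 3.0) -> Angiogram:
    """Read a PNG/TIFF/JPEG export and wrap it as an :class:`Angiogram`."""
    arr = iio.imread(path)
    if str(path).lower().endswith((".jpg", ".jpeg")):
        log.warning(
            "%s is JPEG; lossy compression may shift auto-threshold bounds", path
        )
    px = extract_red_channel(np.asarray(arr))
    scale = field_mm / px.shape[1]
    return Angiogram(px, scale, slab, source_path=str(path))


def _pixels(a: Angiogram | np.ndarray) -> np.ndarray:
    return a.pixels if isinstance(a, Angiogram) else np.asarray(a)


def auto_threshold_default(a: Angiogram | np.ndarray) -> ThresholdBounds:
    """Iterative-intermeans (IsoData-variant) threshold, dark background.

    Starting from the floor of the image mean, iterate
    ``t <- floor((mean(pixels <= t) + mean(pixels > t)) / 2)`` until the
    threshold is unchanged, then return the inclusive bounds
    ``(t + 1, 255)``: with a dark background, the features of interest are
    the bright pixels strictly above the fixed point.
    """
    px = _pixels(a)
    hist = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: constant image has no threshold")
    csum = np.cumsum(hist)
    cmass = np.cumsum(hist * levels)
    total, mass = csum[-1], cmass[-1]

    t = int(px.mean())
    for _ in range(256):
        m_lo = cmass[t] / csum[t]
        m_hi = (mass - cmass[t]) / (total - csum[t])
        t_new = int((m_lo + m_hi) / 2)
        if t_new == t:
            break
        t = t_new
    return ThresholdBounds(lower=t + 1, upper=255, mode="auto_default")


def binarize(a: Angiogram, bounds: ThresholdBounds) -> VesselMask:
    """Mark pixels inside the inclusive [lower, upper] window as vessel."""
    px = a.pixels
    mask = (px >= bounds.lower) & (px <= bounds.upper)
    return VesselMask(mask, a.scale_mm_per_px, bounds_used=bounds, slab=a.slab)


# Tri-color rendering convention for processed figures: vessels black,
# background white, FAZ blue, with FAZ taking precedence over vessel.
_VESSEL_RGB = (0, 0, 0)
_BACKGROUND_RGB = (255, 255, 255)
_FAZ_RGB = (0, 0, 255)


def render_processed(vessels: VesselMask, faz=None) -> np.ndarray:
    """Render the binarized image in the black/white/blue convention."""
    mask = vessels.mask
    if faz is not None and faz.mask.shape != mask.shape:
        raise ValueError("FAZ mask dimensions do not match vessel mask")
    out = np.empty(mask.shape + (3,), dtype=np.uint8)
    out[:] = _BACKGROUND_RGB
    out[mask] = _VESSEL_RGB
    if faz is not None:
        out[faz.mask] = _FAZ_RGB
    return out
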