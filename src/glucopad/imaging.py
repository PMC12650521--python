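"""Color-space conversion, HSV-range thresholding and the color-intensity score.

The readout chemistry (glucose oxidase / peroxidase oxidising TMB) turns the
analysis zone of the paper chip blue, drifting towards green as the reaction
proceeds.  The pipeline quantifies that color in the 8-bit HSV convention used
throughout smartphone image processing: hue in half-degrees (0-179), saturation
and value in 0-255.  A pixel "counts" when its HSV triple falls inside a
configured target range; the intensity score is the in-range pixel fraction of
the reaction zone rescaled to 0-255, which is the predictor of the glucose
calibration line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "HSVRange",
    "BinaryMask",
    "IntensityScore",
    "BLUE_RANGE",
    "GREEN_RANGE",
    "RED_RANGE_PAIR",
    "DegenerateROIError",
    "DimensionError",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "in_range_mask",
    "union_mask",
    "intensity_score",
    "load_image",
    "save_image",
]


class DimensionError(ValueError):
    """Raised for empty images or mismatched mask dimensions."""


class DegenerateROIError(ValueError):
    """Raised when an intensity score is requested over a zero-area ROI."""


@dataclass(frozen=True)
class HSVRange:
    """One target color as an inclusive HSV box.

    Hue wraparound (red) is never encoded as ``lower > upper``; wraparound
    colors are a *list* of two HSVRange values that are unioned downstream.
    """

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        lo, up = self.lower, self.upper
        if not (0 <= lo[0] <= up[0] <= 179):
            raise ValueError(f"hue bounds out of order or outside [0, 179]: {lo[0]}..{up[0]}")
        for i in (1, 2):
            if not (0 <= lo[i] <= up[i] <= 255):
                raise ValueError(f"S/V bounds out of order or outside [0, 255]: {lo[i]}..{up[i]}")

    def contains(self, hsv: tuple[int, int, int]) -> bool:
        return all(self.lower[i] <= hsv[i] <= self.upper[i] for i in range(3))


# Shipped detection ranges: blue and green cover the oxidised-TMB transition,
# the red pair (hue wraps around 0) flags the blood/sample zone.
BLUE_RANGE = HSVRange((90, 50, 50), (130, 255, 255), "blue")
GREEN_RANGE = HSVRange((35, 50, 50), (85, 255, 255), "green")
RED_RANGE_PAIR = (
    HSVRange((0, 50, 50), (10, 255, 255), "red_low"),
    HSVRange((170, 50, 50), (179, 255, 255), "red_high"),
)


@dataclass
class BinaryMask:
    """Per-pixel in-range indicator: values are exactly 0 or 255."""

    pixels: np.ndarray
    white_count: int = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 2 or px.size == 0:
            raise DimensionError("mask must be a non-empty 2-D array")
        bad = ~np.isin(px, (0, 255))
        if bad.any():
            raise ValueError("mask may only contain 0 and 255")
        self.pixels = px
        self.white_count = int(np.count_nonzero(px))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (height, width)

    def as_bool(self) -> np.ndarray:
        return self.pixels == 255


@dataclass(frozen=True)
class IntensityScore:
    """Normalised color-intensity: 255 x (white pixels / ROI pixels)."""

    score: float
    white_count: int
    roi_area: int


def _require_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError(f"expected a HxWx3 image, got shape {arr.shape}")
    return arr.astype(np.float64)


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to 8-bit HSV (hue in half-degrees, 0-179).

    Standard hexcone conversion: V is the channel maximum, S = 255*(max-min)/max
    (0 for achromatic pixels), and hue is computed in degrees, halved, then
    rounded half-up to an integer (179 wraps to 0 at exactly 360 degrees).
    """
    rgb = _require_rgb(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    d = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mx > 0, 255.0 * d / mx, 0.0)
        hue = np.zeros_like(mx)
        chroma = d > 0
        rmax = chroma & (mx == r)
        gmax = chroma & ~rmax & (mx == g)
        bmax = chroma & ~rmax & ~gmax
        hue[rmax] = 60.0 * (((g - b)[rmax] / d[rmax]) % 6.0)
        hue[gmax] = 60.0 * ((b - r)[gmax] / d[gmax] + 2.0)
        hue[bmax] = 60.0 * ((r - g)[bmax] / d[bmax] + 4.0)

    h8 = np.floor(hue / 2.0 + 0.5).astype(np.int64) % 180  # round-half-up
    s8 = np.floor(s + 0.5).astype(np.int64)
    out = np.stack([h8, s8, mx.astype(np.int64)], axis=2)
    return out.astype(np.uint8)


def hsv_to_rgb(h: int, s: int, v: int) -> tuple[int, int, int]:
    """Inverse conversion for a single 8-bit HSV triple (renders, color scales)."""
    if not (0 <= h <= 179 and 0 <= s <= 255 and 0 <= v <= 255):
        raise ValueError(f"HSV triple out of domain: {(h, s, v)}")
    hd = 2.0 * h / 60.0
    c = v / 255.0 * s / 255.0
    x = c * (1.0 - abs(hd % 2.0 - 1.0))
    m = v / 255.0 - c
    sector = [(c, x, 0), (x, c, 0), (0, c, x), (0, x, c), (x, 0, c), (c, 0, x)]
    rp, gp, bp = sector[int(hd) % 6]
    return tuple(int(round(255.0 * (u + m))) for u in (rp, gp, bp))


def in_range_mask(hsv: np.ndarray, hsv_range: HSVRange) -> BinaryMask:
    """Binary mask: 255 where all three channels lie inside the range, inclusive."""
    arr = np.asarray(hsv)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
        raise DimensionError(f"expected a HxWx3 HSV image, got shape {arr.shape}")
    lo = np.asarray(hsv_range.lower)
    up = np.asarray(hsv_range.upper)
    inside = np.all((arr >= lo) & (arr <= up), axis=2)
    return BinaryMask(np.where(inside, 255, 0).astype(np.uint8))


def union_mask(masks: list[BinaryMask]) -> BinaryMask:
    """Pixelwise OR of binary masks (e.g. blue + green during the TMB transition)."""
    if not masks:
        raise ValueError("union of zero masks is undefined")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise DimensionError(f"mask dimensions differ: {m.shape} vs {shape}")
    stacked = np.stack([m.pixels for m in masks])
    return BinaryMask(stacked.max(axis=0))


def intensity_score(mask: BinaryMask, roi_area: int) -> IntensityScore:
    """Color-intensity score of a mask over an ROI of ``roi_area`` pixels.

    The raw white-pixel count is proportional to the reacted color present but
    depends on image resolution; dividing by the ROI area and rescaling to the
    0-255 axis makes the score resolution-invariant.  The raw count is retained
    alongside.
    """
    if roi_area <= 0:
        raise DegenerateROIError("ROI area must be positive")
    if mask.white_count > roi_area:
        raise ValueError(
            f"white_count {mask.white_count} exceeds ROI area {roi_area}"
        )
    return IntensityScore(
        score=255.0 * mask.white_count / roi_area,
        white_count=mask.white_count,
        roi_area=int(roi_area),
    )


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as an 8-bit RGB array; alpha channels are dropped with a warning."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            warnings.warn(f"{path}: alpha channel dropped", stacklevel=2)
        rgb = im.convert("RGB")
        return np.asarray(rgb, dtype=np.uint8)


def save_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(image, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(f"expected a HxWx3 image, got shape {arr.shape}")
    Image.fromarray(arr, mode="RGB").save(path)
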