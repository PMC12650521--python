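"""Chip localisation, blood/reaction region labeling and ROI extraction.

The measurement photo shows a shaped paper strip (sample disc, capillary
channel, pointed analysis zone) against a darker background.  Localisation is
brightness-based: the paper is the bright object, found by Otsu thresholding
and connected components, with interior colored zones recovered by hole
filling.  Region labeling is purely colorimetric — blood by the red hue pair,
the reacted zone by the blue/green ranges of the TMB chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imaging import (
    BLUE_RANGE,
    GREEN_RANGE,
    RED_RANGE_PAIR,
    BinaryMask,
    HSVRange,
    in_range_mask,
    union_mask,
)

__all__ = [
    "ROI",
    "RegionLabelMap",
    "PixelSampleSet",
    "ChipNotFoundError",
    "NoReactionDetectedError",
    "detect_chip",
    "label_regions",
    "extract_reaction_roi",
    "derive_hsv_range",
    "BACKGROUND",
    "CHIP",
    "BLOOD_ZONE",
    "REACTION_ZONE",
]


class ChipNotFoundError(RuntimeError):
    """No bright paper-like object could be separated from the background."""


class NoReactionDetectedError(RuntimeError):
    """The photo contains a chip but no reacted (blue/green) zone.

    Distinct from a zero intensity score: it signals an unusable photo rather
    than a measured absence of color.
    """


BACKGROUND, CHIP, BLOOD_ZONE, REACTION_ZONE = 0, 1, 2, 3

# Below this brightness spread there is no object/background contrast to segment.
_MIN_CONTRAST = 16
# A candidate chip smaller than this fraction of the frame is rejected as noise.
_MIN_CHIP_FRACTION = 0.01


@dataclass
class ROI:
    """A region of interest stored as a boolean pixel mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("ROI mask must be 2-D with positive area")
        self.mask = m

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), max bounds exclusive."""
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        r = np.where(rows)[0]
        c = np.where(cols)[0]
        return int(r[0]), int(c[0]), int(r[-1]) + 1, int(c[-1]) + 1


@dataclass
class RegionLabelMap:
    """Per-pixel label in {background, chip, blood_zone, reaction_zone}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.uint8)
        if lab.ndim != 2 or lab.max(initial=0) > REACTION_ZONE:
            raise ValueError("labels must be 2-D with values 0..3")
        self.labels = lab

    def zone_mask(self, zone: int) -> np.ndarray:
        return self.labels == zone


@dataclass(frozen=True)
class PixelSampleSet:
    """User-selected HSV triples from which a detection range is derived."""

    samples: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("sample set must be non-empty")
        for h, s, v in self.samples:
            if not (0 <= h <= 179 and 0 <= s <= 255 and 0 <= v <= 255):
                raise ValueError(f"sample outside the HSV domain: {(h, s, v)}")


def detect_chip(image: np.ndarray) -> ROI:
    """Locate the paper chip as the largest bright connected component.

    The global threshold comes from Otsu's bimodal-histogram criterion on the
    brightness (max-channel) plane; interior holes — the colored sample and
    reaction zones sit darker than the paper — are filled back into the chip.
    Ties between equally large components break by leftmost, then topmost
    bounding box.

    Raises ChipNotFoundError when the frame has no brightness contrast (blank
    frames included) or when the brightest component covers under 1% of it.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
        raise ValueError(f"expected a HxWx3 RGB image, got shape {arr.shape}")
    gray = arr.max(axis=2).astype(np.uint8)
    if int(gray.max()) - int(gray.min()) < _MIN_CONTRAST:
        raise ChipNotFoundError("no brightness contrast between chip and background")

    thr = threshold_otsu(gray)
    bright = gray > thr
    if not bright.any():
        raise ChipNotFoundError("no above-threshold pixels")

    comp = cc_label(bright, connectivity=2)
    props = regionprops(comp)
    props.sort(key=lambda p: (-p.area, p.bbox[1], p.bbox[0]))
    best = props[0]
    if best.area < _MIN_CHIP_FRACTION * gray.size:
        raise ChipNotFoundError(
            f"largest bright component covers {best.area} px "
            f"(< 1% of {gray.size} px frame)"
        )
    chip = ndimage.binary_fill_holes(comp == best.label)
    return ROI(chip)


def label_regions(
    hsv: np.ndarray,
    chip: ROI,
    *,
    blood_ranges: tuple[HSVRange, ...] = RED_RANGE_PAIR,
    reaction_ranges: tuple[HSVRange, ...] = (BLUE_RANGE, GREEN_RANGE),
) -> RegionLabelMap:
    """Label chip pixels as blood (red pair) or reaction zone (blue/green).

    Empty zones are legal; the caller decides whether that is an error.
    Blood takes precedence over reaction for the (hue-disjoint, hence
    practically impossible) case of a pixel matching both.
    """
    arr = np.asarray(hsv)
    if arr.shape[:2] != chip.mask.shape:
        raise ValueError("HSV image and chip ROI dimensions differ")
    blood = union_mask([in_range_mask(arr, r) for r in blood_ranges]).as_bool()
    reaction = union_mask([in_range_mask(arr, r) for r in reaction_ranges]).as_bool()

    labels = np.zeros(chip.mask.shape, dtype=np.uint8)
    labels[chip.mask] = CHIP
    labels[chip.mask & blood] = BLOOD_ZONE
    labels[chip.mask & reaction & ~blood] = REACTION_ZONE
    return RegionLabelMap(labels)


def extract_reaction_roi(labels: RegionLabelMap, hsv: np.ndarray | None = None) -> ROI:
    """Largest connected component (8-connectivity) of reaction-zone pixels.

    Ties on area break by larger mean saturation (when the HSV image is
    provided), then by leftmost bounding box.
    """
    reaction = labels.zone_mask(REACTION_ZONE)
    if not reaction.any():
        raise NoReactionDetectedError("no reacted (blue/green) pixels on the chip")
    comp = cc_label(reaction, connectivity=2)
    props = regionprops(comp)

    def mean_sat(p) -> float:
        if hsv is None:
            return 0.0
        return float(np.asarray(hsv)[..., 1][comp == p.label].mean())

    props.sort(key=lambda p: (-p.area, -mean_sat(p), p.bbox[1], p.bbox[0]))
    return ROI(comp == props[0].label)


def derive_hsv_range(
    samples: PixelSampleSet,
    margin: tuple[int, int, int] = (0, 0, 0),
    label: str = "derived",
) -> HSVRange:
    """Semi-automatic range construction from user-picked pixels.

    The user clicks pixels inside the expected color; the detection range is
    their componentwise min/max envelope widened by a per-channel margin and
    clipped to the HSV domain.  Every input sample lies inside the result.
    """
    if any(m < 0 for m in margin):
        raise ValueError("margins must be non-negative")
    arr = np.asarray(samples.samples, dtype=np.int64)
    lo = arr.min(axis=0) - np.asarray(margin)
    up = arr.max(axis=0) + np.asarray(margin)
    lo = np.clip(lo, 0, [179, 255, 255])
    up = np.clip(up, 0, [179, 255, 255])
    return HSVRange(tuple(int(x) for x in lo), tuple(int(x) for x in up), label)


def reaction_mask(
    hsv: np.ndarray,
    roi: ROI,
    ranges: tuple[HSVRange, ...],
) -> BinaryMask:
    """In-range mask restricted to an ROI (the mask the score is counted on)."""
    full = union_mask([in_range_mask(hsv, r) for r in ranges]).as_bool()
    return BinaryMask(np.where(full & roi.mask, 255, 0).astype(np.uint8))
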