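"""Synthetic chip photographs with exact ground truth.

Renders the shaped paper strip — a round sample zone joined by a capillary
channel to a pointed analysis zone — as a smartphone-style RGB frame: bright
paper on a darker benchtop, the sample zone filled with blood red, and the
analysis zone developed to a chosen degree.

Color development is model-based, not photochemical: a calibration line is
inverted to turn a target glucose concentration into an intended intensity
(0-255), and exactly that fraction of the analysis-zone pixels receives an
in-range blue/green color.  The reacted pixels grow from the pointed tip as a
V-shaped front, the pattern capillary flow produces on real strips.  Additive
sensor noise and a multiplicative illumination ramp emulate uncontrolled
lighting.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CalibrationModel, reference_models
from .imaging import hsv_to_rgb, save_image

__all__ = [
    "ChipLayout",
    "SyntheticSpec",
    "GroundTruth",
    "SpecError",
    "render_chip",
    "make_calibration_ladder",
    "analysis_zone_pixel_area",
    "analysis_zone_area_mm2",
    "write_ground_truth",
]

# Fixed render palette (8-bit sRGB).
PAPER_RGB = (245, 243, 240)  # near-white, saturation far below any range
BACKGROUND_RGB = (58, 58, 60)  # dark benchtop
BLOOD_RGB = (188, 30, 36)  # hue 179 (red pair), S 214, V 188
REACTED_S = 224
REACTED_V = 205
_PAPER_TEXTURE_SD = 2.0  # mild fiber texture, always on


class SpecError(ValueError):
    """Invalid synthetic spec (e.g. target glucose not invertible to [0, 255])."""


@dataclass(frozen=True)
class ChipLayout:
    """Physical strip geometry in mm plus the render scale.

    Defaults are the refined device design: 5 mm sample zone, 10 x 2 mm
    channel, 4 mm analysis zone with a pointed termination.  20 px/mm is
    roughly a phone shot from 10 cm.
    """

    sample_zone_diameter: float = 5.0
    channel_length: float = 10.0
    channel_width: float = 2.0
    analysis_zone_diameter: float = 4.0
    pointed_tip: bool = True
    pixels_per_mm: float = 20.0
    margin_mm: float = 2.0

    def __post_init__(self) -> None:
        dims = (
            self.sample_zone_diameter, self.channel_length, self.channel_width,
            self.analysis_zone_diameter, self.margin_mm,
        )
        if any(d <= 0 for d in dims):
            raise SpecError("all layout dimensions must be positive")
        if self.pixels_per_mm < 4:
            raise SpecError("pixels_per_mm must be at least 4")


def _default_model() -> CalibrationModel:
    return reference_models()[0]


@dataclass(frozen=True)
class SyntheticSpec:
    layout: ChipLayout = ChipLayout()
    target_glucose: float = 90.0  # mg/dL
    generative_model: CalibrationModel = field(default_factory=_default_model)
    reacted_hue: int = 108  # half-degrees; TMB blue
    noise_sd: float = 5.0  # additive, 8-bit channel units
    illumination_gradient: float = 0.10  # multiplicative drop across the frame
    seed: int = 0

    def intended_intensity(self) -> float:
        """Invert the generative line: the intensity the render must express."""
        m = self.generative_model
        return (self.target_glucose - m.intercept) / m.slope


@dataclass
class GroundTruth:
    """What the render actually contains, for oracle-style tests."""

    chip_mask: np.ndarray  # bool, whole strip
    blood_mask: np.ndarray  # bool, sample zone
    reaction_mask: np.ndarray  # bool, analysis zone (reacted or not)
    chip_polygon: list[list[float]]  # [x, y] pixel coordinates, 0-based
    blood_polygon: list[list[float]]
    reaction_polygon: list[list[float]]
    target_glucose: float
    intended_intensity: float


def _geometry(layout: ChipLayout) -> dict:
    """Rasterise the strip geometry; pixel centers sampled at (i+0.5)/scale mm."""
    ppm = layout.pixels_per_mm
    m = layout.margin_mm
    r_s = layout.sample_zone_diameter / 2.0
    r_a = layout.analysis_zone_diameter / 2.0
    w2 = layout.channel_width / 2.0
    length = layout.channel_length

    cx_s = m + r_s
    chan_x0, chan_x1 = m + r_s, m + 2 * r_s + length + r_a  # overlaps both zones
    cx_a = m + 2 * r_s + length + r_a
    tip_len = 2 * r_a if layout.pointed_tip else 0.0
    x_apex = cx_a + tip_len

    width_mm = x_apex + m if layout.pointed_tip else cx_a + r_a + m
    height_mm = 2 * max(r_s, r_a) + 2 * m
    y0 = height_mm / 2.0
    W = int(round(width_mm * ppm))
    H = int(round(height_mm * ppm))

    xs = (np.arange(W) + 0.5) / ppm
    ys = (np.arange(H) + 0.5) / ppm
    X, Y = np.meshgrid(xs, ys)
    dy = np.abs(Y - y0)

    blood = (X - cx_s) ** 2 + (Y - y0) ** 2 <= r_s**2
    channel = (X >= chan_x0) & (X <= chan_x1) & (dy <= w2)
    half_disc = ((X - cx_a) ** 2 + (Y - y0) ** 2 <= r_a**2) & (X <= cx_a)
    if layout.pointed_tip:
        tip = (X >= cx_a) & (X <= x_apex) & (dy <= r_a * (1.0 - (X - cx_a) / tip_len))
        zone = half_disc | tip
    else:
        zone = (X - cx_a) ** 2 + (Y - y0) ** 2 <= r_a**2
    chip = blood | channel | zone

    # V-shaped fill priority: distance of the leftward-opening chevron from the tip
    priority = (x_apex - X) + 0.8 * dy

    return {
        "shape": (H, W), "ppm": ppm, "y0": y0,
        "cx_s": cx_s, "r_s": r_s, "cx_a": cx_a, "r_a": r_a, "x_apex": x_apex,
        "blood": blood, "channel": channel, "zone": zone, "chip": chip,
        "priority": priority,
    }


def analysis_zone_pixel_area(layout: ChipLayout) -> int:
    """Pixel area of the rasterised analysis zone at the layout's scale.

    This is the scoring denominator the measurement pipeline uses; the
    renderer expresses the intended in-range fraction over the same count, so
    the convention is shared end to end.
    """
    return int(np.count_nonzero(_geometry(layout)["zone"]))


def analysis_zone_area_mm2(layout: ChipLayout) -> float:
    """Closed-form area of the analysis zone (half-disc plus tip triangle)."""
    r = layout.analysis_zone_diameter / 2.0
    if layout.pointed_tip:
        return math.pi * r**2 / 2.0 + 2.0 * r**2
    return math.pi * r**2


def _circle_polygon(cx: float, cy: float, r: float, n: int = 64) -> list[list[float]]:
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return [[cx + r * math.cos(a), cy + r * math.sin(a)] for a in ang]


def _zone_polygon(g: dict) -> list[list[float]]:
    ppm = g["ppm"]
    cx, y0, r = g["cx_a"] * ppm, g["y0"] * ppm, g["r_a"] * ppm
    arc = [
        [cx + r * math.cos(a), y0 + r * math.sin(a)]
        for a in np.linspace(math.pi / 2, 3 * math.pi / 2, 33)
    ]
    apex = [[g["x_apex"] * ppm, y0]]
    return arc + apex if g["x_apex"] > g["cx_a"] else arc


def _chip_polygon(g: dict) -> list[list[float]]:
    # coarse outline: sample circle, channel corners, zone outline
    ppm = g["ppm"]
    pts = _circle_polygon(g["cx_s"] * ppm, g["y0"] * ppm, g["r_s"] * ppm, 32)
    pts += _zone_polygon(g)
    return pts


def render_chip(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one chip photograph and its ground truth.

    The analysis zone receives exactly round(f * N) in-range pixels, where
    f = intended_intensity / 255 and N is the zone's rasterised pixel count;
    the reacted pixels are those nearest the tip under the V-shaped priority
    field (row-major tie-break), so the front is connected and deterministic.
    """
    intended = spec.intended_intensity()
    if not 0.0 <= intended <= 255.0:
        raise SpecError(
            f"target glucose {spec.target_glucose} inverts to intensity "
            f"{intended:.1f}, outside [0, 255]"
        )
    g = _geometry(spec.layout)
    H, W = g["shape"]
    rng = np.random.default_rng(spec.seed)

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    img[g["chip"]] = PAPER_RGB
    img[g["blood"]] = BLOOD_RGB

    # paper fiber texture on unreacted paper only (never touches colored zones)
    paper_only = g["chip"] & ~g["blood"] & ~g["zone"]
    img[paper_only] += rng.normal(0.0, _PAPER_TEXTURE_SD, (int(paper_only.sum()), 3))

    zone_idx = np.flatnonzero(g["zone"].ravel())
    n_zone = zone_idx.size
    k = int(round(intended / 255.0 * n_zone))
    if k > 0:
        order = np.argsort(g["priority"].ravel()[zone_idx], kind="stable")
        reacted_flat = zone_idx[order[:k]]
        reacted_rgb = hsv_to_rgb(spec.reacted_hue, REACTED_S, REACTED_V)
        img.reshape(-1, 3)[reacted_flat] = reacted_rgb

    if spec.illumination_gradient > 0.0:
        ramp = 1.0 - spec.illumination_gradient * (np.arange(W) / max(W - 1, 1))
        img *= ramp[None, :, None]
    if spec.noise_sd > 0.0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        chip_mask=g["chip"],
        blood_mask=g["blood"],
        reaction_mask=g["zone"],
        chip_polygon=_chip_polygon(g),
        blood_polygon=_circle_polygon(g["cx_s"] * g["ppm"], g["y0"] * g["ppm"],
                                      g["r_s"] * g["ppm"]),
        reaction_polygon=_zone_polygon(g),
        target_glucose=spec.target_glucose,
        intended_intensity=intended,
    )
    return out, gt


def make_calibration_ladder(
    concentrations: list[float], template: SyntheticSpec
) -> list[tuple[np.ndarray, GroundTruth]]:
    """One render per concentration; per-rung seeds derive from the template seed."""
    out = []
    for i, conc in enumerate(concentrations):
        seed_i = (1_000_003 * template.seed + i) % 2**31
        spec_i = SyntheticSpec(
            layout=template.layout,
            target_glucose=float(conc),
            generative_model=template.generative_model,
            reacted_hue=template.reacted_hue,
            noise_sd=template.noise_sd,
            illumination_gradient=template.illumination_gradient,
            seed=seed_i,
        )
        out.append(render_chip(spec_i))
    return out


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """JSON sidecar: polygons as 0-based [x, y] pixel coordinates plus scalars."""
    doc = {
        "target_glucose_mg_dl": gt.target_glucose,
        "intended_intensity": gt.intended_intensity,
        "chip_polygon": gt.chip_polygon,
        "blood_polygon": gt.blood_polygon,
        "reaction_polygon": gt.reaction_polygon,
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def render_to_files(spec: SyntheticSpec, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Render and write the PNG plus its ground-truth sidecar."""
    img, gt = render_chip(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / f"{stem}.png"
    sidecar = out / f"{stem}.json"
    save_image(img, png)
    write_ground_truth(gt, sidecar)
    return png, sidecar
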