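"""Clinical banding, detection-range check, flow-rate arithmetic and reports.

Readings are banded against a configurable normal window (default 70-110
mg/dL, both ends inclusive): Low below it, High above it.  Reports are
machine-readable JSON records plus a rendered reference color scale (a PNG
strip of the blue shades the chip develops across the concentration range),
so a result can be interpreted visually without the app.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .imaging import HSVRange, IntensityScore, hsv_to_rgb, save_image

__all__ = [
    "Band",
    "BandConfig",
    "GlucoseReading",
    "classify",
    "check_detection_range",
    "compute_flow_rate",
    "build_report",
    "write_report",
    "reading_from_json",
    "render_reference_scale",
    "batch_summary",
    "REPORT_SCHEMA_KEYS",
]


class Band(str, Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"

    @property
    def index(self) -> int:
        return ("low", "normal", "high").index(self.value)


@dataclass(frozen=True)
class BandConfig:
    """Clinical band boundaries; the normal window is inclusive on both ends."""

    low_upper: float = 70.0  # mg/dL: below this is Low
    normal_upper: float = 110.0  # mg/dL: above this is High

    def __post_init__(self) -> None:
        if not 0 < self.low_upper < self.normal_upper:
            raise ValueError(
                f"need 0 < low_upper < normal_upper, got {self.low_upper}, {self.normal_upper}"
            )


def classify(glucose: float, bands: BandConfig = BandConfig()) -> Band:
    """Low if g < low_upper; Normal if low_upper <= g <= normal_upper; else High."""
    if not math.isfinite(glucose):
        raise ValueError("glucose must be finite")
    if glucose < bands.low_upper:
        return Band.LOW
    if glucose <= bands.normal_upper:
        return Band.NORMAL
    return Band.HIGH


def check_detection_range(glucose: float, model: CalibrationModel) -> bool:
    """True iff the concentration lies within the model's detection range, inclusive."""
    lo, hi = model.detection_range
    return lo <= glucose <= hi


def compute_flow_rate(distance_mm: float, elapsed_s: float) -> float:
    """Capillary flow rate distance/time in mm/s, reported to three decimals."""
    if distance_mm <= 0 or elapsed_s <= 0:
        raise ValueError("distance and elapsed time must be positive")
    return round(distance_mm / elapsed_s, 3)


@dataclass(frozen=True)
class GlucoseReading:
    """Final result of one measurement, with the provenance of its intensity."""

    glucose: float  # mg/dL
    band: Band
    in_detection_range: bool
    intensity: IntensityScore
    model_id: str  # sample_type of the calibration used
    timestamp: str = ""  # ISO 8601; empty until stamped

    def stamped(self) -> "GlucoseReading":
        ts = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        return GlucoseReading(
            self.glucose, self.band, self.in_detection_range,
            self.intensity, self.model_id, ts,
        )


REPORT_SCHEMA_KEYS = frozenset(
    {"glucose_mg_dl", "band", "in_detection_range", "intensity", "model_id",
     "timestamp", "hsv_ranges", "mask_stats"}
)


def build_report(
    reading: GlucoseReading,
    mask_stats: dict | None = None,
    hsv_ranges: list[HSVRange] | None = None,
) -> dict:
    """Structured, JSON-serialisable record of a reading.

    Includes the full intensity provenance (raw white count and ROI area, not
    just the normalised score) and the HSV ranges that produced the mask.
    """
    return {
        "glucose_mg_dl": reading.glucose,
        "band": reading.band.value,
        "in_detection_range": reading.in_detection_range,
        "intensity": {
            "score": reading.intensity.score,
            "white_count": reading.intensity.white_count,
            "roi_area": reading.intensity.roi_area,
        },
        "model_id": reading.model_id,
        "timestamp": reading.timestamp,
        "hsv_ranges": [
            {"label": r.label, "lower": list(r.lower), "upper": list(r.upper)}
            for r in (hsv_ranges or [])
        ],
        "mask_stats": mask_stats or {},
    }


def reading_from_json(doc: dict) -> GlucoseReading:
    """Rebuild a GlucoseReading from a report document (serialisation inverse)."""
    it = doc["intensity"]
    return GlucoseReading(
        glucose=float(doc["glucose_mg_dl"]),
        band=Band(doc["band"]),
        in_detection_range=bool(doc["in_detection_range"]),
        intensity=IntensityScore(
            score=float(it["score"]),
            white_count=int(it["white_count"]),
            roi_area=int(it["roi_area"]),
        ),
        model_id=str(doc["model_id"]),
        timestamp=str(doc.get("timestamp", "")),
    )


def write_report(
    report: dict,
    out_dir: str | Path,
    stem: str = "reading",
    scale_png: bool = True,
) -> list[Path]:
    """Write the JSON record (and the reference color scale PNG) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / f"{stem}.json"]
    paths[0].write_text(json.dumps(report, indent=2) + "\n")
    if scale_png:
        png = out / f"{stem}_scale.png"
        render_reference_scale(png)
        paths.append(png)
    return paths


def render_reference_scale(
    path: str | Path,
    detection_range: tuple[float, float] = (50.0, 140.0),
    n_steps: int = 10,
    swatch_px: int = 24,
) -> None:
    """Render the visual comparison scale: blue swatches deepening with glucose.

    Each swatch keeps the TMB blue hue and deepens saturation with
    concentration across the detection range, mirroring how the chip darkens.
    """
    lo, hi = detection_range
    rows = []
    for k in range(n_steps):
        frac = k / (n_steps - 1)
        s = int(round(60 + frac * 195))  # pale to saturated blue
        v = int(round(235 - frac * 60))
        rows.append(hsv_to_rgb(108, s, v))
    strip = np.zeros((n_steps * swatch_px, 3 * swatch_px, 3), dtype=np.uint8)
    for k, rgb in enumerate(rows):
        strip[k * swatch_px:(k + 1) * swatch_px, :] = rgb
    save_image(strip, path)


def batch_summary(reports: list[dict]) -> pd.DataFrame:
    """One row per reading: the batch CSV table (image column added by the CLI)."""
    return pd.DataFrame(
        {
            "glucose_mg_dl": [r["glucose_mg_dl"] for r in reports],
            "band": [r["band"] for r in reports],
            "in_detection_range": [r["in_detection_range"] for r in reports],
            "intensity_score": [r["intensity"]["score"] for r in reports],
            "white_count": [r["intensity"]["white_count"] for r in reports],
            "roi_area": [r["intensity"]["roi_area"] for r in reports],
            "model_id": [r["model_id"] for r in reports],
        }
    )
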