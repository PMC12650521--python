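"""Linear intensity-to-glucose calibration: fit, store, apply, evaluate.

The device's response model is strictly linear over its detection range
(~50-140 mg/dL): Glucose [mg/dL] = slope x intensity + intercept, fitted by
ordinary least squares with glucose as the response.  Two reference models
ship with the package — one characterised on whole blood, one on plasma from
the same specimens; the lines are near-parallel with a constant offset
because residual red cells inflate the whole-blood color intensity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationPair",
    "CalibrationModel",
    "GlucosePrediction",
    "SingularFitError",
    "DEFAULT_DETECTION_RANGE",
    "fit_calibration",
    "predict_glucose",
    "reference_models",
    "reference_pairs",
    "evaluate_model",
    "compare_models",
    "read_pairs",
    "write_pairs",
    "read_model",
    "write_model",
]

DEFAULT_DETECTION_RANGE = (50.0, 140.0)


class SingularFitError(ValueError):
    """All intensities identical: the calibration line is undetermined."""


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration point: measured color intensity vs reference glucose."""

    intensity: float  # 0-255 color-intensity score
    glucose_ref: float  # mg/dL, reference method

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 255.0:
            raise ValueError(f"intensity {self.intensity} outside [0, 255]")
        if not self.glucose_ref > 0:
            raise ValueError(f"reference glucose must be positive, got {self.glucose_ref}")


@dataclass(frozen=True)
class CalibrationModel:
    slope: float  # mg/dL per intensity unit
    intercept: float  # mg/dL
    sample_type: str = "whole_blood"  # whole_blood | plasma
    r_squared: float | None = None
    rmse: float | None = None  # mg/dL
    detection_range: tuple[float, float] = DEFAULT_DETECTION_RANGE
    fixed: bool = False  # built-in reference model, not refittable in place

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and self.slope != 0.0):
            raise ValueError("slope must be finite and nonzero")
        lo, hi = self.detection_range
        if not lo < hi:
            raise ValueError(f"detection range must satisfy low < high, got {lo}..{hi}")


class GlucosePrediction(NamedTuple):
    glucose: float  # mg/dL, one decimal
    in_detection_range: bool


def fit_calibration(
    pairs: list[CalibrationPair],
    sample_type: str = "whole_blood",
    detection_range: tuple[float, float] = DEFAULT_DETECTION_RANGE,
) -> CalibrationModel:
    """Ordinary least squares, glucose regressed on intensity.

    Requires at least two pairs with at least two distinct intensities.
    Populates r_squared (None when the glucose values have zero variance) and
    rmse (root mean square of the fit residuals, mg/dL).
    """
    if len(pairs) < 2:
        raise ValueError("need at least two calibration pairs")
    x = [p.intensity for p in pairs]
    y = [p.glucose_ref for p in pairs]
    if len(set(x)) < 2:
        raise SingularFitError("all intensities identical; line is undetermined")
    res = stats.linregress(x, y)
    model = CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        sample_type=sample_type,
        detection_range=detection_range,
    )
    rmse, r2 = evaluate_model(model, pairs)
    return replace(model, rmse=rmse, r_squared=r2)


def predict_glucose(model: CalibrationModel, intensity: float) -> GlucosePrediction:
    """Apply the calibration line; concentration reported to one decimal.

    Values outside the model's detection range (including negative ones) are
    returned as-is with the flag lowered — never silently clamped, since the
    strip's range bounds are approximate.
    """
    raw = model.slope * intensity + model.intercept
    glucose = round(raw, 1)
    lo, hi = model.detection_range
    return GlucosePrediction(glucose, lo <= glucose <= hi)


def reference_models() -> tuple[CalibrationModel, CalibrationModel]:
    """Built-in (whole_blood, plasma) calibration lines of the characterised device.

    Whole blood: g = 1.4686 x intensity - 157.16
    Plasma:      g = 1.5278 x intensity - 194.35
    Marked fixed: refitting produces a new model rather than mutating these.
    """
    wb = CalibrationModel(1.4686, -157.16, "whole_blood", fixed=True)
    pl = CalibrationModel(1.5278, -194.35, "plasma", fixed=True)
    return wb, pl


# Reference characterisation dataset of the device: eight specimens measured in
# triplicate on chip as whole blood and as plasma from the same draw.  Columns:
# commercial-kit glucose (mg/dL), mean chip color intensity, chip-measured
# glucose (mg/dL) produced by the corresponding reference line.
_REFERENCE_DATA = {
    "whole_blood": [
        # (kit_glucose, intensity, chip_glucose)
        (50.0, 140.3, 48.9),
        (71.0, 159.3, 76.8),
        (87.0, 148.7, 61.2),
        (88.0, 158.3, 75.4),
        (128.0, 174.3, 98.9),
        (72.48, 179.3, 106.2),
        (74.31, 183.7, 112.6),
        (135.0, 192.7, 125.8),
    ],
    "plasma": [
        (50.0, 160.3, 50.6),
        (71.0, 158.0, 47.0),
        (87.0, 165.0, 57.7),
        (88.0, 187.3, 91.9),
        (128.0, 167.0, 60.8),
        (72.48, 175.0, 73.0),
        (74.31, 182.3, 84.2),
        (135.0, 193.0, 100.5),
    ],
}


def reference_pairs(
    sample_type: str = "whole_blood", reference: str = "chip"
) -> list[CalibrationPair]:
    """The bundled characterisation pairs for one sample type.

    ``reference`` selects the glucose column: "chip" (device-line readings, the
    column the reference models reproduce) or "kit" (commercial enzymatic kit).
    """
    if sample_type not in _REFERENCE_DATA:
        raise ValueError(f"unknown sample type {sample_type!r}")
    idx = {"kit": 0, "chip": 2}[reference]
    return [
        CalibrationPair(intensity=row[1], glucose_ref=row[idx])
        for row in _REFERENCE_DATA[sample_type]
    ]


def evaluate_model(
    model: CalibrationModel, pairs: list[CalibrationPair]
) -> tuple[float, float | None]:
    """(rmse, r_squared) of a model's predictions on held pairs.

    r_squared is None when the pairs' glucose values have zero variance.
    """
    if not pairs:
        raise ValueError("need at least one pair to evaluate")
    n = len(pairs)
    residuals = [p.glucose_ref - (model.slope * p.intensity + model.intercept) for p in pairs]
    rmse = math.sqrt(sum(r * r for r in residuals) / n)
    mean_g = sum(p.glucose_ref for p in pairs) / n
    ss_tot = sum((p.glucose_ref - mean_g) ** 2 for p in pairs)
    if ss_tot == 0.0:
        return rmse, None
    ss_res = sum(r * r for r in residuals)
    return rmse, 1.0 - ss_res / ss_tot


def compare_models(
    a: CalibrationModel, b: CalibrationModel
) -> tuple[float, float]:
    """(slope difference, vertical offset) of b relative to a.

    The offset is evaluated at the midpoint of the shared detection range —
    the natural summary when two lines are near-parallel.
    """
    lo = max(a.detection_range[0], b.detection_range[0])
    hi = min(a.detection_range[1], b.detection_range[1])
    mid_g = (lo + hi) / 2.0
    # midpoint expressed on the intensity axis of each line's own domain:
    # evaluate both lines at the intensity where line a hits mid-range glucose.
    mid_i = (mid_g - a.intercept) / a.slope
    offset = (b.slope * mid_i + b.intercept) - (a.slope * mid_i + a.intercept)
    return b.slope - a.slope, offset


# ---------------------------------------------------------------------------
# delimited-text and model serialisation


def read_pairs(path: str | Path) -> list[CalibrationPair]:
    """Read calibration pairs from headered delimited text.

    Required columns: intensity, glucose_mg_dl.  An optional replicate column
    is accepted and ignored for fitting.
    """
    df = pd.read_csv(path)
    missing = {"intensity", "glucose_mg_dl"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        CalibrationPair(float(r.intensity), float(r.glucose_mg_dl))
        for r in df.itertuples(index=False)
    ]


def write_pairs(pairs: list[CalibrationPair], path: str | Path) -> None:
    pd.DataFrame(
        {"intensity": [p.intensity for p in pairs],
         "glucose_mg_dl": [p.glucose_ref for p in pairs]}
    ).to_csv(path, index=False)


def write_model(model: CalibrationModel, path: str | Path) -> None:
    doc = {
        "slope": model.slope,
        "intercept": model.intercept,
        "sample_type": model.sample_type,
        "r_squared": model.r_squared,
        "rmse": model.rmse,
        "detection_range": list(model.detection_range),
        "fixed": model.fixed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    try:
        return CalibrationModel(
            slope=float(doc["slope"]),
            intercept=float(doc["intercept"]),
            sample_type=str(doc.get("sample_type", "whole_blood")),
            r_squared=doc.get("r_squared"),
            rmse=doc.get("rmse"),
            detection_range=tuple(doc.get("detection_range", DEFAULT_DETECTION_RANGE)),
            fixed=bool(doc.get("fixed", False)),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: not a valid calibration model document") from exc
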