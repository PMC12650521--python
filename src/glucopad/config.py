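"""Run configuration: HSV ranges, bands, model selection, chip layout.

A run is fully described by one JSON document; every key has a shipped
default, and CLI flags override file values (flag > file > default).

Schema (all keys optional)::

    {
      "ranges": {
        "blue":  {"lower": [90, 50, 50],  "upper": [130, 255, 255]},
        "green": {"lower": [35, 50, 50],  "upper": [85, 255, 255]},
        "red":   [{"lower": [0, 50, 50],   "upper": [10, 255, 255]},
                  {"lower": [170, 50, 50], "upper": [179, 255, 255]}]
      },
      "bands": {"low_upper": 70, "normal_upper": 110},
      "detection_range": [50, 140],
      "mask_mode": "union",              // union | blue | green
      "model": "whole_blood",            // whole_blood | plasma | path to model file
      "layout": {"sample_zone_diameter": 5, "channel_length": 10,
                 "channel_width": 2, "analysis_zone_diameter": 4,
                 "pointed_tip": true, "pixels_per_mm": 20},
      "seed": 0
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from .calibration import (
    DEFAULT_DETECTION_RANGE,
    CalibrationModel,
    read_model,
    reference_models,
)
from .imaging import BLUE_RANGE, GREEN_RANGE, RED_RANGE_PAIR, HSVRange
from .report import BandConfig
from .synthetic import ChipLayout

__all__ = ["RunConfig", "load_config", "resolve_model"]

MASK_MODES = ("union", "blue", "green")


@dataclass(frozen=True)
class RunConfig:
    blue: HSVRange = BLUE_RANGE
    green: HSVRange = GREEN_RANGE
    red_pair: tuple[HSVRange, HSVRange] = RED_RANGE_PAIR
    bands: BandConfig = BandConfig()
    detection_range: tuple[float, float] = DEFAULT_DETECTION_RANGE
    mask_mode: str = "union"
    model: str = "whole_blood"  # name or model-file path
    layout: ChipLayout = ChipLayout()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_mode not in MASK_MODES:
            raise ValueError(f"mask_mode must be one of {MASK_MODES}")

    def scoring_ranges(self) -> tuple[HSVRange, ...]:
        """The HSV ranges the intensity score counts, per mask mode."""
        return {
            "union": (self.blue, self.green),
            "blue": (self.blue,),
            "green": (self.green,),
        }[self.mask_mode]


def _parse_range(doc: dict, label: str) -> HSVRange:
    return HSVRange(tuple(doc["lower"]), tuple(doc["upper"]), label)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional JSON file plus keyword overrides."""
    cfg = RunConfig()
    if path is not None:
        doc = json.loads(Path(path).read_text())
        kwargs: dict = {}
        ranges = doc.get("ranges", {})
        if "blue" in ranges:
            kwargs["blue"] = _parse_range(ranges["blue"], "blue")
        if "green" in ranges:
            kwargs["green"] = _parse_range(ranges["green"], "green")
        if "red" in ranges:
            kwargs["red_pair"] = tuple(
                _parse_range(r, f"red_{i}") for i, r in enumerate(ranges["red"])
            )
        if "bands" in doc:
            kwargs["bands"] = BandConfig(**doc["bands"])
        if "detection_range" in doc:
            kwargs["detection_range"] = tuple(doc["detection_range"])
        for key in ("mask_mode", "model", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        if "layout" in doc:
            kwargs["layout"] = ChipLayout(**doc["layout"])
        cfg = replace(cfg, **kwargs)
    if overrides:
        cfg = replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
    return cfg


def resolve_model(spec: str, detection_range: tuple[float, float]) -> CalibrationModel:
    """Turn a model spec (built-in name or file path) into a CalibrationModel."""
    wb, pl = reference_models()
    if spec == "whole_blood":
        model = wb
    elif spec == "plasma":
        model = pl
    elif Path(spec).exists():
        model = read_model(spec)
    else:
        raise ValueError(f"unknown model {spec!r}: not a built-in name or file")
    if tuple(detection_range) != tuple(model.detection_range):
        model = replace(model, detection_range=tuple(detection_range))
    return model
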