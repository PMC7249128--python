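"""Pipeline configuration: one documented YAML file for every parameter.

Defaults reproduce the published processing constants — 5×5 depth
median, CLAHE clip 40 with an 8×8 tile grid, histogram peak range 50,
flood band −10/+30, 15×2 upright closing kernel, contour area floor
600 — plus the rig geometry.  ``histogram.low_limit`` and
``histogram.count_difference`` have no published values; their defaults
(10 and 200) are package choices and deliberately live in the config so
they stay visible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .detection import DetectionParams
from .geometry import CameraModel
from .segmentation import FloodParams, HistogramParams

__all__ = ["PipelineConfig", "default_config_yaml"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the harvest-run pipeline."""

    camera: CameraModel = field(default_factory=CameraModel)
    histogram: HistogramParams = field(default_factory=HistogramParams)
    flood: FloodParams = field(default_factory=FloodParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    median_kernel: int = 5
    clahe_clip_limit: float = 40.0
    clahe_tiles: tuple[int, int] = (8, 8)
    histogram_scope: str = "masked"
    gnss_clock_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.histogram_scope not in ("masked", "full"):
            raise ValueError("histogram_scope must be 'masked' or 'full'")

    def to_dict(self) -> dict:
        return {
            "camera": dataclasses.asdict(self.camera),
            "histogram": dataclasses.asdict(self.histogram),
            "flood": dataclasses.asdict(self.flood),
            "detection": {
                "min_area": self.detection.min_area,
                "close_kernel": list(self.detection.close_kernel),
                "close_iterations": self.detection.close_iterations,
            },
            "median_kernel": self.median_kernel,
            "clahe": {
                "clip_limit": self.clahe_clip_limit,
                "tiles": list(self.clahe_tiles),
            },
            "histogram_scope": self.histogram_scope,
            "gnss_clock_offset_s": self.gnss_clock_offset_s,
        }

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "PipelineConfig":
        data = dict(data or {})
        clahe = data.get("clahe", {})
        det = data.get("detection", {})
        if "close_kernel" in det:
            det = {**det, "close_kernel": tuple(det["close_kernel"])}
        return cls(
            camera=CameraModel(**data.get("camera", {})),
            histogram=HistogramParams(**data.get("histogram", {})),
            flood=FloodParams(**data.get("flood", {})),
            detection=DetectionParams(**det),
            median_kernel=data.get("median_kernel", 5),
            clahe_clip_limit=clahe.get("clip_limit", 40.0),
            clahe_tiles=tuple(clahe.get("tiles", (8, 8))),
            histogram_scope=data.get("histogram_scope", "masked"),
            gnss_clock_offset_s=data.get("gnss_clock_offset_s", 0.0),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        if hasattr(path_or_text, "read"):
            text = path_or_text.read()
        else:
            try:
                with open(path_or_text) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))


def default_config_yaml() -> str:
    """The full default configuration as YAML text."""
    return PipelineConfig().to_yaml()
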