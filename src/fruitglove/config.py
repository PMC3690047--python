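"""Pipeline configuration: defaults, YAML loading, strict validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping

import yaml

from .vision import AREA_POLY_DEFAULT, CameraModel

__all__ = ["PipelineConfig", "SegmentationConfig", "GradingConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SegmentationConfig:
    theta: float = 0.7
    sigma: float = 25.0
    # Pre-smoothing is off by default: blurring stretches the object edge
    # into a shallow ramp where a column grazes the boundary tangentially,
    # letting the region growing climb out; the affinity's sigma already
    # absorbs pixel noise.
    smooth_sigma: float = 0.0
    ttl_init: int = 30
    dot_score_threshold: float = 60.0
    dot_min_red: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 1.0:
            raise ConfigError("theta must lie in (0, 1]")
        if self.sigma <= 0 or self.ttl_init <= 0:
            raise ConfigError("sigma and ttl_init must be positive")


@dataclass
class GradingConfig:
    on_kpa: float = 20.0
    min_duration_s: float = 1.0
    valid_ratio: float = 0.5
    variety: str = "tomato"
    variety_threshold_kpa: float = 200.0
    alert_threshold: float = 0.5
    # weighted quality score: per-feature weight and ideal (lo, hi) range
    weights: dict[str, float] = field(
        default_factory=lambda: {"pressure_kPa": 1.0, "volume_cm3": 1.0}
    )
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"pressure_kPa": (20.0, 100.0), "volume_cm3": (50.0, 250.0)}
    )

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("weights must be non-negative")
        self.ranges = {k: tuple(v) for k, v in self.ranges.items()}


@dataclass
class PipelineConfig:
    """Everything the end-to-end measurement needs, in one validated block."""

    camera: CameraModel = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    grading: GradingConfig = field(default_factory=GradingConfig)
    area_poly: tuple[float, ...] = AREA_POLY_DEFAULT
    laser_range_cm: tuple[float, float] = (3.0, 7.3)
    ir_range_cm: tuple[float, float] = (5.0, 25.0)

    def __post_init__(self) -> None:
        if self.camera is None:
            self.camera = CameraModel.from_fov(640, 480, 48.0, 2.5)
        self.area_poly = tuple(self.area_poly)
        self.laser_range_cm = tuple(self.laser_range_cm)
        self.ir_range_cm = tuple(self.ir_range_cm)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(data)
        if "camera" in kwargs and isinstance(kwargs["camera"], Mapping):
            cam = dict(kwargs["camera"])
            if "fov_deg" in cam:
                kwargs["camera"] = CameraModel.from_fov(
                    cam.pop("width_px"), cam.pop("height_px"), cam.pop("fov_deg"),
                    cam.pop("baseline_cm", 2.5),
                )
                if cam:
                    raise ConfigError(f"unknown camera keys: {sorted(cam)}")
            else:
                kwargs["camera"] = _from_mapping(CameraModel, cam)
        if isinstance(kwargs.get("segmentation"), Mapping):
            kwargs["segmentation"] = _from_mapping(SegmentationConfig, kwargs["segmentation"])
        if isinstance(kwargs.get("grading"), Mapping):
            kwargs["grading"] = _from_mapping(GradingConfig, kwargs["grading"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)
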