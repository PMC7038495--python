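"""Pipeline configuration: every numeric parameter in one structured object.

The defaults reproduce the study conditions the package was designed around:
hourly frames averaged into one background per day, CLAHE + bilateral
enhancement, absolute-difference segmentation, a 532-long global feature
vector (7 Hu + 13 Haralick + 8x8x8 color histogram) and an 80/20 stratified
split with capped balanced augmentation (x37, cap 3034).

A configuration can be loaded from / saved to a YAML file; CLI flags
override individual fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "DEFAULT_CONFIG"]


@dataclass
class ResizeConfig:
    # printed working size of the source camera's frames after reduction;
    # (864, 1296) would be the exact quarter of 3456x5184 — both usable
    target_height: int = 964
    target_width: int = 1296
    enabled: bool = False  # synthetic scenes are generated at working size


@dataclass
class EnhanceConfig:
    clahe_clip: float = 2.0
    clahe_grid: tuple[int, int] = (8, 8)
    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 75.0
    bilateral_sigma_space: float = 75.0


@dataclass
class SegmentConfig:
    threshold: int = 40  # chosen by scanning values on synthetic fixtures
    # (operation, kernel_size, iterations), applied in order
    morphology: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("closing", 3, 1), ("opening", 3, 1), ("dilation", 3, 1)]
    )
    min_area: int = 50
    # subtract against a background passed through the same enhancement as
    # the observation frame: CLAHE remaps intensities globally, so comparing
    # an enhanced frame with a raw background biases the whole difference
    # image; enhancing both sides cancels the remapping away from objects
    enhance_background: bool = True


@dataclass
class FeatureConfig:
    histogram_bins: int = 8       # per channel -> 512 joint bins
    haralick_levels: int = 32     # gray-level quantization of the GLCM
    haralick_distance: int = 1
    mask_crops: bool = False      # whole-box crops keep local context


@dataclass
class DatasetConfig:
    train_fraction: float = 0.8
    augment_per_original: int = 37
    augment_class_cap: int = 3034
    rotation_max_deg: float = 25.0
    brightness_range: tuple[float, float] = (0.7, 1.3)
    zoom_range: tuple[float, float] = (0.8, 1.2)


@dataclass
class EvaluationConfig:
    cv_folds: int = 10


@dataclass
class PipelineConfig:
    resize: ResizeConfig = field(default_factory=ResizeConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = PipelineConfig()

_SECTIONS = {
    "resize": ResizeConfig,
    "enhance": EnhanceConfig,
    "segment": SegmentConfig,
    "features": FeatureConfig,
    "dataset": DatasetConfig,
    "evaluation": EvaluationConfig,
}

_TUPLE_FIELDS = {"clahe_grid", "brightness_range", "zoom_range"}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing fields keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, cls in _SECTIONS.items():
        if section not in raw:
            continue
        sub = getattr(cfg, section)
        for key, value in (raw[section] or {}).items():
            if not hasattr(sub, key):
                raise ValueError(f"unknown config key {section}.{key}")
            if key in _TUPLE_FIELDS:
                value = tuple(value)
            elif key == "morphology":
                value = [tuple(v) for v in value]
            setattr(sub, key, value)
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
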