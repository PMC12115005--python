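"""YAML pipeline configuration: scene, training, localization and eval blocks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import TrainConfig
from .errors import ConfigurationError
from .localization import LocalizationConfig
from .synthetic import SceneConfig


@dataclass
class EvalConfig:
    conf_threshold: float = 0.5
    iou_threshold: float = 0.5
    mode: str = "paper"


@dataclass
class PathsConfig:
    data_dir: str = "data"
    out_dir: str = "out"
    checkpoint: str = "model"


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)


def _build(cls, block: dict, name: str):
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigurationError(f"bad key in {name!r} block: {exc}") from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing blocks and keys fall back to defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    scene_block = dict(raw.get("scene", {}))
    for key in ("image_size", "class_names", "class_prevalences"):
        if key in scene_block and isinstance(scene_block[key], list):
            scene_block[key] = tuple(scene_block[key])
    train_block = dict(raw.get("train", {}))
    if "optimizer_betas" in train_block:
        train_block["optimizer_betas"] = tuple(train_block["optimizer_betas"])
    return PipelineConfig(
        scene=_build(SceneConfig, scene_block, "scene"),
        train=_build(TrainConfig, train_block, "train"),
        localization=_build(LocalizationConfig, dict(raw.get("localization", {})), "localization"),
        eval=_build(EvalConfig, dict(raw.get("eval", {})), "eval"),
        paths=_build(PathsConfig, dict(raw.get("paths", {})), "paths"),
    )
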