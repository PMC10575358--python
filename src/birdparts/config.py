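"""Run configuration: YAML files with strict (unknown-key-rejecting) schema."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detector import Hyperparams, NetworkConfig


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "paths": {"data", "output"},
    "model": {"num_classes", "width_multiple", "depth_multiple", "input_size",
              "res2net_scale", "reduction_ratio", "seed", "anchors"},
    "train": {"epochs", "batch_size", "lr", "seed", "box_weight", "obj_weight",
              "cls_weight", "anchor_match_threshold"},
    "eval": {"conf_threshold", "nms_iou", "map_iou", "map_conf_threshold"},
    "fusion": {"step_hundredths"},
    "augment": {"brightness_factor", "noise_sigma", "seed",
                "swap_wings_on_flip"},
}

_EVAL_DEFAULTS = {"conf_threshold": 0.25, "nms_iou": 0.45, "map_iou": 0.5,
                  "map_conf_threshold": 0.001}


@dataclass
class RunConfig:
    paths: dict = field(default_factory=dict)
    model: NetworkConfig = field(default_factory=NetworkConfig)
    train: Hyperparams = field(default_factory=Hyperparams)
    eval: dict = field(default_factory=lambda: dict(_EVAL_DEFAULTS))
    fusion_step: int = 1
    augment: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        return {"paths": self.paths, "model": self.model.to_dict(),
                "train": vars(self.train).copy(), "eval": self.eval,
                "fusion": {"step_hundredths": self.fusion_step},
                "augment": self.augment}


def _check_keys(section: str, keys, allowed):
    unknown = set(keys) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section "
                          f"'{section}'")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; unknown sections or keys raise ConfigError."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
    for section, values in (overrides or {}).items():
        raw.setdefault(section, {}).update(values)
    _check_keys("<root>", raw, set(_SCHEMA))
    for section, values in raw.items():
        if not isinstance(values, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        _check_keys(section, values, _SCHEMA[section])
    model_kw = dict(raw.get("model", {}))
    if "anchors" in model_kw:
        model_kw["anchors"] = tuple(tuple(a) for a in model_kw["anchors"])
    cfg = RunConfig(
        paths=dict(raw.get("paths", {})),
        model=NetworkConfig(**model_kw),
        train=Hyperparams(**raw.get("train", {})),
        eval={**_EVAL_DEFAULTS, **raw.get("eval", {})},
        fusion_step=int(raw.get("fusion", {}).get("step_hundredths", 1)),
        augment=dict(raw.get("augment", {})),
    )
    for key in ("conf_threshold", "nms_iou", "map_iou", "map_conf_threshold"):
        v = cfg.eval[key]
        if not 0 <= v <= 1:
            raise ConfigError(f"eval.{key} must be in [0, 1], got {v}")
    if not (isinstance(cfg.fusion_step, int) and cfg.fusion_step > 0
            and 100 % cfg.fusion_step == 0):
        raise ConfigError("fusion.step_hundredths must divide 100")
    return cfg
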