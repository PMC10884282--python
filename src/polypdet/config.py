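"""Run configuration: YAML schema, defaults, and resolution.

Precedence: explicit CLI flag > YAML value > built-in default. Every run
writes its fully-resolved config (and seed) next to its outputs so results
are reproducible from the artifact alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .detector import DetectorConfig

__all__ = ["ConfigError", "DEFAULTS", "load_config", "resolve_config",
           "detector_config_from", "save_resolved"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "model": {
        "width_multiple": 0.25,
        "depth_multiple": 0.33,
        "num_classes": 1,
        "attention": True,
        "attention_reduction": 16,
        "learn_alphas": True,
    },
    "loss": {
        "box_loss": "gwd",      # 'gwd' | 'ciou'
        "tau": 1.0,
        "gwd_squash": "log",    # 'log' | 'linear'
        "weights": [0.5, 1.0, 1.0],  # cls, obj, box
    },
    "data": {
        "manifest": None,        # path to manifest.yaml
        "synthetic": {           # used by `generate`
            "n": 200,
            "size": 128,
            "scenario_mix": {"typical": 0.4, "low_contrast": 0.2,
                             "small": 0.2, "multi": 0.2},
        },
    },
    "train": {
        "epochs": 12,
        "batch_size": 8,
        "lr": 5e-3,
        "img_size": 128,
        "anchors": "auto",       # 'auto' (k-means on the training labels) | 'default'
    },
    "eval": {
        "iou_thresholds": [0.3, 0.5],
        "conf_thresh": 0.25,
        "nms_iou": 0.45,
    },
}


def _deep_update(base: dict, upd: dict, path: str = "") -> dict:
    for k, v in upd.items():
        if k not in base:
            raise ConfigError(f"unknown config key {path + k!r}")
        if isinstance(base[k], dict) and isinstance(v, dict):
            _deep_update(base[k], v, path + k + ".")
        else:
            base[k] = v
    return base


def resolve_config(user: dict | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    if user:
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a YAML mapping")
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    _validate(cfg)
    return cfg


def load_config(path=None, overrides: dict | None = None) -> dict:
    user = None
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            user = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {p}: {exc}") from None
    return resolve_config(user, overrides)


def _validate(cfg: dict) -> None:
    m, lo, tr = cfg["model"], cfg["loss"], cfg["train"]
    if m["width_multiple"] <= 0 or m["depth_multiple"] <= 0:
        raise ConfigError("model.width_multiple and model.depth_multiple must be positive")
    if lo["box_loss"] not in ("gwd", "ciou"):
        raise ConfigError(f"loss.box_loss must be 'gwd' or 'ciou', got {lo['box_loss']!r}")
    if lo["tau"] < 1.0:
        raise ConfigError(f"loss.tau must be >= 1, got {lo['tau']}")
    if len(lo["weights"]) != 3 or any(w < 0 for w in lo["weights"]):
        raise ConfigError("loss.weights must be three nonnegative numbers (cls, obj, box)")
    if tr["epochs"] < 1 or tr["batch_size"] < 1:
        raise ConfigError("train.epochs and train.batch_size must be >= 1")
    if tr["img_size"] % 32:
        raise ConfigError(f"train.img_size must be divisible by 32, got {tr['img_size']}")
    for t in cfg["eval"]["iou_thresholds"]:
        if not 0.0 < t < 1.0:
            raise ConfigError(f"eval.iou_thresholds entries must be in (0,1), got {t}")


def detector_config_from(cfg: dict) -> DetectorConfig:
    m, lo = cfg["model"], cfg["loss"]
    return DetectorConfig(
        width_multiple=m["width_multiple"],
        depth_multiple=m["depth_multiple"],
        num_classes=m["num_classes"],
        attention=m["attention"],
        attention_reduction=m["attention_reduction"],
        learn_alphas=m["learn_alphas"],
        box_loss=lo["box_loss"],
        tau=lo["tau"],
        gwd_squash=lo["gwd_squash"],
        loss_weights=tuple(lo["weights"]),
    )


def save_resolved(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
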