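"""YAML configuration: one file with per-stage blocks.

Recognised blocks: ``phantom``, ``preprocess``, ``network``,
``supervision``, ``loss``, ``train``, ``postprocess``.  Each block maps
onto the corresponding config dataclass; absent blocks fall back to
defaults.
"""

from __future__ import annotations

import yaml

from .network import NetworkConfig
from .phantom import PhantomConfig
from .pipeline import TrainConfig
from .preprocess import PreprocessConfig

__all__ = [
    "load_config",
    "phantom_config",
    "preprocess_config",
    "network_config",
    "train_config",
]

_TUPLE_KEYS = {
    "shape", "spacing", "hu_window", "target_spacing", "augmentation_axes",
    "dilation_rates", "pyramid_kernels", "patch_size",
}


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, (list, tuple)) else v
            for k, v in d.items()}


def load_config(path: str | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping of blocks")
    return cfg


def phantom_config(cfg: dict, **overrides) -> PhantomConfig:
    return PhantomConfig(**{**_tuplify(cfg.get("phantom", {})), **overrides})


def preprocess_config(cfg: dict, **overrides) -> PreprocessConfig:
    return PreprocessConfig(**{**_tuplify(cfg.get("preprocess", {})), **overrides})


def network_config(cfg: dict, **overrides) -> NetworkConfig:
    return NetworkConfig(**{**_tuplify(cfg.get("network", {})), **overrides})


def train_config(cfg: dict, **overrides) -> TrainConfig:
    block = _tuplify(cfg.get("train", {}))
    loss_block = cfg.get("loss", {})
    if loss_block:
        block.setdefault("loss", loss_block.get("name", "tversky"))
        params = {k: v for k, v in loss_block.items() if k != "name"}
        if params:
            block.setdefault("loss_params", params)
    post = cfg.get("postprocess", {})
    if "min_volume_mm3" in post:
        block.setdefault("postprocess_min_volume", post["min_volume_mm3"])
    return TrainConfig(**{**block, **overrides})
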