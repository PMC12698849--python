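"""YAML experiment configuration: loading, defaults, and resolution."""

from __future__ import annotations

import yaml

from .protocol import TrainConfig

DATA_DEFAULTS = {
    "source": "synthetic",     # or a class-per-subdirectory folder path
    "n_per_class": 200,
    "n_classes": 4,
    "image_size": 32,
    "test_fraction": 0.2,
    "seed": 0,
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return raw


def resolve(raw: dict) -> tuple[TrainConfig, dict]:
    """Split a raw config mapping into a TrainConfig and a data section with
    defaults filled in."""
    data_cfg = {**DATA_DEFAULTS, **raw.get("data", {})}
    train_raw = dict(raw.get("train", {}))
    cfg = TrainConfig.from_dict(train_raw)
    return cfg, data_cfg


def dump_resolved(cfg: TrainConfig, data_cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"train": cfg.to_dict(), "data": data_cfg}, fh,
                       sort_keys=False)
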