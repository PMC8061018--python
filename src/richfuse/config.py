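"""Layered run configuration and seed fan-out.

Precedence is defaults <- config file <- command-line overrides.  Every
randomized stage receives a seed derived deterministically from the global
seed and the stage name, so one ``--seed`` reproduces a whole pipeline.
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dim_raising import RaiserConfig
from .fusion import FusionHeadSpec, TrainingSchedule
from .image_backbone import BackboneSpec, TrainConfig
from .preprocessing import PatchPlan
from .synthetic import CohortParams, PAPERSIZE_PRESET, TEST_PRESET

__all__ = ["DEFAULTS", "load_config", "op_seed", "schedule_from_config",
           "cohort_params_from_config", "patch_plan_from_config", "config_hash"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out": "runs",
    "verbosity": "info",
    "raiser": {
        "method": "denoising_autoencoder_l1",
        "layer_widths": [29, 290, 435, 580, 435, 290, 29],
        "lambda": None,
        "corruption_rate": 0.2,
        "epochs": 200,
        "learning_rate": 1e-3,
        "batch_size": 32,
    },
    "backbone": {
        "stage_channels": [64, 128, 256, 512, 512],
        "convs_per_stage": [2, 2, 3, 3, 3],
        "input_side": 224,
    },
    "backbone_train": {"epochs": 10, "learning_rate": 1e-3, "batch_size": 32},
    "head": {"layer_widths": [500, 100, 2], "epochs": 80,
             "learning_rate": 1e-3, "batch_size": 32},
    "fusion": {"source_stages": [3, 4, 5]},
    "preprocess": {
        "entries": [[224, 40], [512, 20], [1024, 10], [1536, 5]],
        "include_whole_resize": True,
        "output_side": 224,
    },
    "evaluation": {"train_fraction": 0.8, "n_seeds": 3},
    "simulate": {"preset": "test"},
}


def _merge(base: dict, update: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in update.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            valid = ", ".join(sorted(base))
            raise KeyError(f"unknown config key {here!r}; valid keys here: {valid}")
        if isinstance(base[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def _apply_overrides(cfg: dict, overrides: Mapping[str, Any]) -> dict:
    for dotted, value in overrides.items():
        tree: dict = {}
        node = tree
        parts = dotted.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
        cfg = _merge(cfg, tree)
    return cfg


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Resolve a full run configuration (defaults <- file <- overrides)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _apply_overrides(cfg, overrides)
    return cfg


def op_seed(global_seed: int, op_name: str) -> int:
    """Stable per-operation seed derived from the global seed and a name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(op_name.encode())) % 2**31


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def schedule_from_config(cfg: Mapping, seed: int | None = None) -> TrainingSchedule:
    r = cfg["raiser"]
    b = cfg["backbone"]
    bt = cfg["backbone_train"]
    h = cfg["head"]
    seed = cfg["seed"] if seed is None else seed
    return TrainingSchedule(
        raiser_config=RaiserConfig(
            method=r["method"], layer_widths=tuple(r["layer_widths"]),
            lam=r["lambda"], corruption_rate=r["corruption_rate"],
            epochs=r["epochs"], learning_rate=r["learning_rate"],
            batch_size=r["batch_size"], seed=op_seed(seed, "raiser"),
        ),
        backbone_spec=BackboneSpec(
            stage_channels=tuple(b["stage_channels"]),
            convs_per_stage=tuple(b["convs_per_stage"]),
            input_side=b["input_side"], seed=op_seed(seed, "backbone"),
        ),
        backbone_train=TrainConfig(
            epochs=bt["epochs"], learning_rate=bt["learning_rate"],
            batch_size=bt["batch_size"],
        ),
        head_spec=FusionHeadSpec(tuple(h["layer_widths"])),
        head_epochs=h["epochs"], head_learning_rate=h["learning_rate"],
        head_batch_size=h["batch_size"],
        source_stages=tuple(cfg["fusion"]["source_stages"]),
        seed=seed,
    )


def cohort_params_from_config(cfg: Mapping) -> CohortParams:
    preset = cfg["simulate"]["preset"]
    if preset == "test":
        return TEST_PRESET
    if preset == "papersize":
        return PAPERSIZE_PRESET
    raise ValueError(f"unknown simulate preset {preset!r}; valid: test, papersize")


def patch_plan_from_config(cfg: Mapping) -> PatchPlan:
    p = cfg["preprocess"]
    return PatchPlan(
        entries=tuple((int(s), int(c)) for s, c in p["entries"]),
        include_whole_resize=bool(p["include_whole_resize"]),
        output_side=int(p["output_side"]),
    )
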