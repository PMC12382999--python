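"""Nested run configuration with YAML loading and strict key validation.

Precedence: built-in defaults < config file < explicit overrides.
Unknown keys are rejected with the offending key path in the error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["MotionConfig", "ModelConfig", "MhgnConfig", "HeadConfig",
           "TrackerConfig", "TrainConfig", "ArenaDefaults", "RunConfig",
           "load_config"]


@dataclass
class MotionConfig:
    window: int = 5
    alpha: float = 0.1
    beta: float = 0.01
    lam: float = 1.0
    ridge: float = 1e-5
    iters: int = 3
    presmooth: float = 1.0
    stat_window: int = 61
    k1: float = 1.0
    k2: float = 2.5
    min_rho: float = 1e-6


@dataclass
class ModelConfig:
    hidden: int = 32
    depths: tuple = (1, 1, 1, 1)
    widths: tuple = (8, 16, 32, 64)
    pe_bands: int = 8                    # L
    stages_used: tuple = (0, 1, 2, 3)
    share_backbone: bool = False


@dataclass
class MhgnConfig:
    depth: int = 1
    heads: int = 2
    k_spatial: int = 8
    mem_momentum: float = 0.9
    spatial_cross: bool = True
    decode_heads: int = 8                # M
    decode_points: int = 4


@dataclass
class HeadConfig:
    focal_alpha: float = 2.0
    focal_beta: float = 4.0
    fusion_gamma: float = 2.0
    fusion_eps: float = 1e-6
    motion_noise_std: float = 0.0
    score_thresh: float = 0.3
    max_det: int = 50


@dataclass
class TrackerConfig:
    match_thresh: float = 0.3
    redet_thresh: float = 0.4
    max_inactive_frames: int = 30
    spawn_score_thresh: float = 0.4
    gate_radius: float = 16.0
    redet_gate_scale: float = 1.5
    use_motion: bool = True      # ablation: motion decoupling stream
    use_mhgn: bool = True        # ablation: graph fusion (off -> depth 0)
    use_redet: bool = True       # ablation: re-detection of lost tracks


@dataclass
class TrainConfig:
    optimizer: str = "adamw"
    lr: float = 2e-4
    batch_size: int = 16
    epochs: int = 300
    schedule: str = "cosine"
    warmup_steps: int = 1000
    weight_decay: float = 0.05
    input_size: int = 512
    flip: bool = True
    rotation_deg: float = 30.0


@dataclass
class ArenaDefaults:
    scenario: str = "easy_separated"
    n_frames: int = 30


@dataclass
class RunConfig:
    seed: int = 0
    device: str = "cpu"
    motion: MotionConfig = field(default_factory=MotionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    mhgn: MhgnConfig = field(default_factory=MhgnConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    arena: ArenaDefaults = field(default_factory=ArenaDefaults)


def _apply(obj, data: dict, path: str = "") -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, val in data.items():
        where = f"{path}.{key}" if path else key
        if key not in fields:
            raise KeyError(f"unknown config key: {where}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur):
            if not isinstance(val, dict):
                raise TypeError(f"config key {where} expects a mapping")
            _apply(cur, val, where)
        else:
            want = type(cur)
            if isinstance(cur, bool):
                if not isinstance(val, bool):
                    raise TypeError(f"config key {where} expects a bool")
            elif isinstance(cur, int) and not isinstance(val, (int,)):
                raise TypeError(f"config key {where} expects an int")
            elif isinstance(cur, float):
                if not isinstance(val, (int, float)):
                    raise TypeError(f"config key {where} expects a number")
                val = float(val)
            elif isinstance(cur, tuple):
                if not isinstance(val, (list, tuple)):
                    raise TypeError(f"config key {where} expects a sequence")
                val = tuple(val)
            elif isinstance(cur, str) and not isinstance(val, str):
                raise TypeError(f"config key {where} expects a string")
            setattr(obj, key, val)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, and overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise TypeError("config file must contain a mapping")
        _apply(cfg, data)
    if overrides:
        _apply(cfg, overrides)
    return cfg
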