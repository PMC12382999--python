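"""Synthetic arena simulator: many near-identical blob agents with erratic
accelerations, sharp turns, trajectory crossings and occlusions under a static
camera.

The simulator reproduces the statistical regime the tracker targets
(appearance similarity, impulsive motion, frequent overlap); it makes no
attempt at photorealistic animal rendering.  Agents follow piecewise-constant
velocity with Bernoulli-timed random impulses and Gaussian heading jitter,
bouncing off reflective walls.  Rendering sums per-agent Gaussian blobs plus
sensor noise.  Output is bit-reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["ArenaConfig", "SimulatedSequence", "simulate", "scenario",
           "write_mot_gt", "SCENARIOS"]


@dataclass(frozen=True)
class ArenaConfig:
    width: int = 96
    height: int = 96
    n_agents: int = 5
    radius: float = 3.0
    radius_jitter: float = 0.3
    base_speed: float = 1.5
    max_speed: float = 4.0
    impulse_rate: float = 0.1        # per-agent per-frame probability
    impulse_mag: float = 1.5
    turn_std: float = 0.1            # radians of per-frame heading jitter
    allow_overlap: bool = True
    confine_cells: bool = False      # each agent bounces inside its own cell
    n_frames: int = 30
    noise: float = 0.01
    seed: int = 0
    init_positions: tuple | None = None   # ((x, y), ...) overrides random init
    init_velocities: tuple | None = None

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not (0.0 <= self.impulse_rate <= 1.0):
            raise ValueError("impulse_rate must be in [0, 1]")
        if 4.0 * self.radius >= min(self.width, self.height):
            raise ValueError("agents too large for arena")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class SimulatedSequence:
    frames: list[np.ndarray]                  # H x W float64 in [0, 1]
    records: list[list[tuple]]                # per frame: (id, left, top, w, h)
    trajectories: dict[int, np.ndarray]       # id -> (n_frames, 2) centres
    impulse_count: int
    config: ArenaConfig

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _render(positions: np.ndarray, radii: np.ndarray, amps: np.ndarray,
            cfg: ArenaConfig, rng: np.random.Generator) -> np.ndarray:
    ys, xs = np.mgrid[0:cfg.height, 0:cfg.width].astype(np.float64)
    img = np.full((cfg.height, cfg.width), 0.08)
    for (px, py), r, a in zip(positions, radii, amps):
        s = r / 1.5
        img += a * np.exp(-((xs - px) ** 2 + (ys - py) ** 2) / (2.0 * s * s))
    img += rng.normal(0.0, cfg.noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate(cfg: ArenaConfig) -> SimulatedSequence:
    """Generate a sequence of rendered frames plus exact ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_agents
    radii = cfg.radius + cfg.radius_jitter * rng.standard_normal(n)
    radii = np.clip(radii, 1.5, None)
    amps = 0.75 + 0.1 * rng.standard_normal(n)

    # per-agent bounce boxes (whole arena, or a private cell grid)
    margin = 2.0 * cfg.radius
    if cfg.confine_cells:
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        cw, ch = cfg.width / cols, cfg.height / rows
        bounds = []
        for i in range(n):
            cx, cy = i % cols, i // cols
            bounds.append((cx * cw + margin, (cx + 1) * cw - margin,
                           cy * ch + margin, (cy + 1) * ch - margin))
    else:
        bounds = [(margin, cfg.width - margin, margin, cfg.height - margin)] * n

    pos = np.empty((n, 2))
    if cfg.init_positions is not None:
        pos[:] = np.asarray(cfg.init_positions, dtype=np.float64)
    else:
        for i, (x0, x1, y0, y1) in enumerate(bounds):
            pos[i] = (rng.uniform(x0, x1), rng.uniform(y0, y1))

    if cfg.init_velocities is not None:
        vel = np.asarray(cfg.init_velocities, dtype=np.float64).copy()
    else:
        ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
        vel = cfg.base_speed * np.column_stack([np.cos(ang), np.sin(ang)])

    frames: list[np.ndarray] = []
    records: list[list[tuple]] = []
    trajs = np.empty((cfg.n_frames, n, 2))
    impulses = 0

    for t in range(cfg.n_frames):
        trajs[t] = pos
        frames.append(_render(pos, radii, amps, cfg, rng))
        recs = []
        for i in range(n):
            w = h = 2.0 * float(radii[i] + 1.0)
            recs.append((i + 1, float(pos[i, 0] - w / 2), float(pos[i, 1] - h / 2), w, h))
        records.append(recs)

        # dynamics update (skipped after the last rendered frame is fine,
        # but keeping it makes trajectories extendable)
        hit = rng.random(n) < cfg.impulse_rate
        impulses += int(hit.sum())
        if hit.any():
            ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
            mag = cfg.impulse_mag * rng.random(n)
            vel[hit] += (mag[:, None] * np.column_stack([np.cos(ang), np.sin(ang)]))[hit]
        if cfg.turn_std > 0:
            dth = rng.normal(0.0, cfg.turn_std, size=n)
            ca, sa = np.cos(dth), np.sin(dth)
            vel = np.column_stack([ca * vel[:, 0] - sa * vel[:, 1],
                                   sa * vel[:, 0] + ca * vel[:, 1]])
        speed = np.linalg.norm(vel, axis=1)
        over = speed > cfg.max_speed
        if over.any():
            vel[over] *= (cfg.max_speed / speed[over])[:, None]
        pos = pos + vel
        for i, (x0, x1, y0, y1) in enumerate(bounds):
            for d, (lo, hi) in enumerate(((x0, x1), (y0, y1))):
                if pos[i, d] < lo:
                    pos[i, d] = 2 * lo - pos[i, d]
                    vel[i, d] = -vel[i, d]
                elif pos[i, d] > hi:
                    pos[i, d] = 2 * hi - pos[i, d]
                    vel[i, d] = -vel[i, d]
            np.clip(pos[i], 1.0, [cfg.width - 2.0, cfg.height - 2.0], out=pos[i])

    trajectories = {i + 1: trajs[:, i].copy() for i in range(n)}
    return SimulatedSequence(frames=frames, records=records,
                             trajectories=trajectories,
                             impulse_count=impulses, config=cfg)


SCENARIOS = ("easy_separated", "crossing_pair", "dense_occlusion", "erratic")


def scenario(name: str, seed: int = 0, n_frames: int | None = None) -> ArenaConfig:
    """Curated arena configurations used by the tests and the CLI."""
    if name == "easy_separated":
        cfg = ArenaConfig(width=120, height=80, n_agents=5, radius=2.5,
                          base_speed=1.0, max_speed=1.5, impulse_rate=0.0,
                          impulse_mag=0.0, turn_std=0.08, confine_cells=True,
                          n_frames=20, noise=0.008, seed=seed)
    elif name == "crossing_pair":
        cfg = ArenaConfig(width=96, height=96, n_agents=2, radius=2.5,
                          radius_jitter=0.0, base_speed=1.5, max_speed=2.0,
                          impulse_rate=0.0, impulse_mag=0.0, turn_std=0.0,
                          n_frames=38, noise=0.006, seed=seed,
                          init_positions=((20.0, 48.0), (76.0, 48.0)),
                          init_velocities=((1.5, 0.0), (-1.5, 0.0)))
    elif name == "dense_occlusion":
        cfg = ArenaConfig(width=128, height=128, n_agents=12, radius=3.0,
                          base_speed=2.0, max_speed=4.0, impulse_rate=0.15,
                          impulse_mag=1.5, turn_std=0.25, n_frames=30,
                          noise=0.01, seed=seed)
    elif name == "erratic":
        cfg = ArenaConfig(width=128, height=128, n_agents=4, radius=3.0,
                          base_speed=2.5, max_speed=5.0, impulse_rate=0.3,
                          impulse_mag=2.0, turn_std=0.5, n_frames=30,
                          noise=0.01, seed=seed)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if n_frames is not None:
        cfg = replace(cfg, n_frames=n_frames)
    return cfg


def write_mot_gt(seq: SimulatedSequence, out_dir: str | Path) -> Path:
    """Write frames (PNG) and ground truth in MOTChallenge dialect.

    Frames are 1-based in files, 0-based in memory.  Returns the gt file path.
    """
    out = Path(out_dir)
    (out / "img1").mkdir(parents=True, exist_ok=True)
    gt_path = out / "gt.txt"
    with open(gt_path, "w", encoding="utf-8") as fh:
        for t, recs in enumerate(seq.records):
            for (tid, left, top, w, h) in recs:
                fh.write(f"{t + 1},{tid},{left:.4f},{top:.4f},{w:.4f},{h:.4f},1,1,1\n")
    for t, frame in enumerate(seq.frames):
        iio.imwrite(out / "img1" / f"{t + 1:06d}.png",
                    (np.clip(frame, 0, 1) * 65535).astype(np.uint16))
    meta = asdict(seq.config)
    with open(out / "seqinfo.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return gt_path
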