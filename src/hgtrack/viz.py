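"""Trajectory overlay plotting for tracker output or ground truth."""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_mot import MotRecord

__all__ = ["plot_trajectories"]


def plot_trajectories(records: list[MotRecord], out_path: str | Path,
                      background: np.ndarray | None = None,
                      title: str = "trajectories") -> Path:
    """Overlay per-identity centre trajectories, optionally on a frame."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    tracks: dict[int, list[tuple[int, float, float]]] = defaultdict(list)
    for r in records:
        tracks[r.track_id].append((r.frame, r.left + r.width / 2,
                                   r.top + r.height / 2))
    fig, ax = plt.subplots(figsize=(6, 6))
    if background is not None:
        ax.imshow(background, cmap="gray", vmin=0, vmax=1)
    cmap = plt.get_cmap("tab20")
    for i, (tid, pts) in enumerate(sorted(tracks.items())):
        pts.sort()
        xs = [p[1] for p in pts]
        ys = [p[2] for p in pts]
        ax.plot(xs, ys, "-", color=cmap(i % 20), lw=1.2, label=f"id {tid}")
        ax.plot(xs[-1:], ys[-1:], "o", color=cmap(i % 20), ms=4)
    ax.set_title(title)
    ax.invert_yaxis() if background is None else None
    if len(tracks) <= 12:
        ax.legend(fontsize=7, loc="upper right")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
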