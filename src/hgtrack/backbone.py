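"""Dual-stream multi-scale feature extraction and query projection.

Each modality (appearance image, 2-channel motion raster) runs through a
four-stage pyramid transformer: overlapping strided patch embedding followed
by pre-norm self-attention blocks per stage, at downsampling ratios
{4, 8, 16, 32}.  Stage features are flattened row-major and linearly
projected to the shared hidden width, with multi-band sinusoidal positional
encodings added.  Depths and widths are configurable so tests can run a tiny
randomly initialised instance; no pretrained weights are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import Conv2d, LayerNorm, Linear, MLP, Module, pad2d_br

__all__ = ["FeaturePyramid", "QueryMatrix", "positional_encoding",
           "PositionalEncoder", "Backbone", "QueryProjector", "RATIOS"]

RATIOS = (4, 8, 16, 32)


@dataclass
class FeaturePyramid:
    stages: list[Tensor]          # each (C_s, H_s, W_s)
    modality: str                 # "appearance" | "motion"


@dataclass
class QueryMatrix:
    queries: Tensor               # (N, h)
    modality: str
    stage: int
    coords: np.ndarray            # (N, 2) of (x, y) in stage-grid units

    @property
    def n_tokens(self) -> int:
        return self.queries.shape[0]


def positional_encoding(coords_norm: np.ndarray, bands: int = 8) -> np.ndarray:
    """Raw sinusoidal encoding of normalised (x, y) coordinates.

    For each axis and band l in [0, L): sin(2^l * pi * c), cos(2^l * pi * c).
    Output shape (N, 4L), values in [-1, 1].
    """
    if bands < 1:
        raise ValueError("bands must be >= 1")
    coords_norm = np.asarray(coords_norm, dtype=np.float64)
    freqs = (2.0 ** np.arange(bands)) * np.pi          # (L,)
    args = coords_norm[:, :, None] * freqs             # (N, 2, L)
    enc = np.concatenate([np.sin(args), np.cos(args)], axis=2)  # (N, 2, 2L)
    return enc.reshape(coords_norm.shape[0], 4 * bands)


class PositionalEncoder(Module):
    """Sinusoidal bands followed by a learned linear map to the hidden width."""

    def __init__(self, bands: int, hidden: int, rng: np.random.Generator):
        self.bands = bands
        self.proj = Linear(4 * bands, hidden, rng)

    def forward(self, coords_norm: np.ndarray) -> Tensor:
        return self.proj(Tensor(positional_encoding(coords_norm, self.bands)))


class _Block(Module):
    """Pre-norm transformer block: x += Attn(LN(x)); x += MLP(LN(x))."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.mlp = MLP(dim, 2 * dim, dim, rng)
        self.scale = 1.0 / np.sqrt(dim)

    def forward(self, x: Tensor) -> Tensor:
        z = self.ln1(x)
        q, k, v = self.wq(z), self.wk(z), self.wv(z)
        attn = ((q @ k.T) * self.scale).softmax(axis=-1) @ v
        x = x + attn
        return x + self.mlp(self.ln2(x))


class Backbone(Module):
    """Four-stage pyramid encoder for one modality."""

    def __init__(self, in_channels: int, widths=(8, 16, 32, 64),
                 depths=(1, 1, 1, 1), rng: np.random.Generator | None = None):
        if len(widths) != 4 or len(depths) != 4:
            raise ValueError("widths/depths must have 4 entries")
        rng = rng or np.random.default_rng(0)
        self.widths = tuple(widths)
        self.embeds = []
        self.blocks = []
        cin = in_channels
        for s, (w, d) in enumerate(zip(widths, depths)):
            stride = 4 if s == 0 else 2
            k = 5 if s == 0 else 3
            pad = k // 2
            self.embeds.append(Conv2d(cin, w, k, rng, stride=stride, padding=pad))
            self.blocks.append([_Block(w, rng) for _ in range(d)])
            cin = w

    def forward(self, image: np.ndarray | Tensor, modality: str = "appearance") -> FeaturePyramid:
        """image: (C, H, W) with C in {1, 2, 3}; spatial size padded to /32."""
        x = as_tensor(image)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.size == 0:
            raise ValueError("empty image")
        c, H, W = x.shape
        padH = (-H) % 32
        padW = (-W) % 32
        if padH or padW:
            x = pad2d_br(x, padH, padW)
        stages = []
        for embed, blocks in zip(self.embeds, self.blocks):
            x = embed(x)
            cw, hs, ws = x.shape
            t = x.reshape(cw, hs * ws).T           # (N, C) row-major tokens
            for blk in blocks:
                t = blk(t)
            x = t.T.reshape(cw, hs, ws)
            stages.append(x)
        return FeaturePyramid(stages=stages, modality=modality)


class QueryProjector(Module):
    """Per-stage flatten + linear projection + positional encoding (Eq-style)."""

    def __init__(self, widths, hidden: int, bands: int, rng: np.random.Generator):
        self.hidden = hidden
        self.projs = [Linear(w, hidden, rng) for w in widths]
        self.pe = PositionalEncoder(bands, hidden, rng)

    def forward(self, pyramid: FeaturePyramid, stage: int) -> QueryMatrix:
        if not 0 <= stage < len(pyramid.stages):
            raise ValueError(f"stage must be in [0, {len(pyramid.stages)})")
        feat = pyramid.stages[stage]
        c, hs, ws = feat.shape
        tokens = feat.reshape(c, hs * ws).T                 # row-major flatten
        ys, xs = np.divmod(np.arange(hs * ws), ws)
        coords = np.column_stack([xs, ys]).astype(np.float64)
        norm = (coords + 0.5) / np.array([ws, hs])
        q = self.projs[stage](tokens) + self.pe(norm)
        return QueryMatrix(queries=q, modality=pyramid.modality, stage=stage,
                           coords=coords)
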