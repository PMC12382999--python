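"""Multi-modal heterogeneous graph over detection queries and trajectory
memory, with typed attention message passing and deformable decoding.

Nodes: appearance/motion detection queries of the current frame (D_a, D_m)
and appearance/motion trajectory memory of the previous frame (T_a, T_m;
zero rows at sequence start).  Edges: temporal (D <-> T within modality),
spatial (within frame, relative-position bias, optionally cross-modality)
and heterogeneous (cross-modal between D_a and D_m).  The graph is realised
as typed attention over index sets; no graph library is used.

Attention follows the single-formula form
``softmax(Q Wq (K Wk)^T / sqrt(d)) V Wv`` per edge type, with an additive
MLP bias on relative offsets for spatial edges, and an unnormalised sum over
modalities for heterogeneous edges.  Each encoder round applies
temporal -> spatial -> heterogeneous attention with pre-norm residuals, so
depth 0 is the identity and zero memory contributes a zero temporal update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .backbone import QueryMatrix
from .nn import LayerNorm, Linear, MLP, Module, grid_sample

__all__ = ["HeteroGraph", "FusedQueries", "TypedAttention", "SpatialBias",
           "build_graph", "temporal_attention", "spatial_attention",
           "heterogeneous_attention", "GraphEncoder", "DeformableDecoder"]

FULL_ATTENTION_LIMIT = 64  # below this token count spatial edges are dense


@dataclass
class HeteroGraph:
    d_a: QueryMatrix
    d_m: QueryMatrix
    t_a: Tensor                    # (Nt, h); Nt may be 0
    t_m: Tensor
    neighbors: np.ndarray | None   # (N, k) spatial neighbour indices, or None = dense

    @property
    def n_detection_tokens(self) -> int:
        return self.d_a.n_tokens


@dataclass
class FusedQueries:
    d_a: Tensor
    d_m: Tensor
    t_a: Tensor
    t_m: Tensor
    coords: np.ndarray


def build_graph(d_a: QueryMatrix, d_m: QueryMatrix, t_a, t_m,
                k_spatial: int = 8) -> HeteroGraph:
    """Register node blocks and compute spatial neighbourhoods.

    The two detection streams are pixel-aligned, so heterogeneous edges pair
    tokens at identical grid positions (plus full cross-modal attention in
    the heterogeneous sum).
    """
    if d_a.n_tokens == 0 or d_m.n_tokens == 0:
        raise ValueError("empty detection query set")
    h = d_a.queries.shape[1]
    t_a = as_tensor(t_a if t_a is not None else np.zeros((0, h)))
    t_m = as_tensor(t_m if t_m is not None else np.zeros((0, h)))
    for blk, name in ((d_m.queries, "d_m"), (t_a, "t_a"), (t_m, "t_m")):
        if blk.shape[-1] != h:
            raise ValueError(f"hidden width mismatch for {name}")
    if not np.array_equal(d_a.coords, d_m.coords):
        raise ValueError("appearance/motion token grids must be aligned")
    n = d_a.n_tokens
    neighbors = None
    if n > FULL_ATTENTION_LIMIT:
        c = d_a.coords
        d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        k = min(k_spatial, n)
        neighbors = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return HeteroGraph(d_a=d_a, d_m=d_m, t_a=t_a, t_m=t_m, neighbors=neighbors)


class TypedAttention(Module):
    """Edge-type-specific attention: softmax(Q Wq (K Wk)^T / sqrt(d)) V Wv."""

    def __init__(self, dim: int, rng: np.random.Generator, heads: int = 1):
        if dim % heads:
            raise ValueError("hidden width must be divisible by head count")
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.heads = heads
        self.dim = dim

    def forward(self, q, k, v, bias=None, mask=None) -> Tensor:
        """bias: (heads, Nq, Nk) additive logits; mask: bool (Nq, Nk) allowed."""
        q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
        if k.shape[0] == 0:
            return Tensor(np.zeros((q.shape[0], self.dim)))
        nq, nk = q.shape[0], k.shape[0]
        hd = self.dim // self.heads
        qp = self.wq(q).reshape(nq, self.heads, hd).transpose(1, 0, 2)
        kp = self.wk(k).reshape(nk, self.heads, hd).transpose(1, 0, 2)
        vp = self.wv(v).reshape(nk, self.heads, hd).transpose(1, 0, 2)
        logits = (qp @ kp.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
        if bias is not None:
            logits = logits + bias
        if mask is not None:
            logits = logits + Tensor(np.where(mask, 0.0, -1e9))
        attn = logits.softmax(axis=-1)
        out = attn @ vp                                  # (heads, Nq, hd)
        return out.transpose(1, 0, 2).reshape(nq, self.dim)

    def attention_weights(self, q, k, bias=None, mask=None) -> np.ndarray:
        """Softmax rows (heads, Nq, Nk) for inspection/tests."""
        q, k = as_tensor(q), as_tensor(k)
        nq, nk = q.shape[0], k.shape[0]
        hd = self.dim // self.heads
        qp = self.wq(q).data.reshape(nq, self.heads, hd).transpose(1, 0, 2)
        kp = self.wk(k).data.reshape(nk, self.heads, hd).transpose(1, 0, 2)
        logits = (qp @ kp.transpose(0, 2, 1)) / np.sqrt(hd)
        if bias is not None:
            logits = logits + (bias.data if isinstance(bias, Tensor) else bias)
        if mask is not None:
            logits = logits + np.where(mask, 0.0, -1e9)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


class SpatialBias(Module):
    """phi_ij = MLP(dx_ij, dy_ij): one scalar per head per token pair."""

    def __init__(self, rng: np.random.Generator, heads: int = 1, hidden: int = 16):
        self.net = MLP(2, hidden, heads, rng)
        self.heads = heads

    def forward(self, coords_q: np.ndarray, coords_k: np.ndarray) -> Tensor:
        nq, nk = len(coords_q), len(coords_k)
        delta = (coords_q[:, None, :] - coords_k[None, :, :]).reshape(nq * nk, 2)
        # token coordinates live on a grid, so offsets repeat heavily;
        # evaluate the MLP once per unique offset and gather
        uniq, inv = np.unique(delta, axis=0, return_inverse=True)
        out = self.net(Tensor(uniq))                     # (n_unique, heads)
        return out[inv].reshape(nq, nk, self.heads).transpose(2, 0, 1)


def temporal_attention(q, k, v, params: TypedAttention) -> Tensor:
    """Modality-specific temporal attention between query and memory blocks."""
    return params(q, k, v)


def spatial_attention(q, k, v, coords_q, coords_k, params: TypedAttention,
                      bias_net: SpatialBias, mask=None) -> Tensor:
    """Spatial attention with relative-position bias phi(dx, dy).

    The bias depends only on coordinate differences, so a global shift of all
    coordinates leaves it unchanged.
    """
    bias = bias_net(np.asarray(coords_q, float), np.asarray(coords_k, float))
    return params(q, k, v, bias=bias, mask=mask)


def heterogeneous_attention(q, kv_blocks, params: TypedAttention) -> Tensor:
    """Unnormalised sum over modalities of per-modality softmax attention."""
    out = None
    for k, v in kv_blocks:
        term = params(q, k, v)
        out = term if out is None else out + term
    return out


class _Round(Module):
    """One temporal -> spatial -> heterogeneous pass with pre-norm residuals."""

    def __init__(self, dim: int, rng: np.random.Generator, spatial_cross: bool = True):
        self.attn_t_a = TypedAttention(dim, rng)
        self.attn_t_m = TypedAttention(dim, rng)
        self.attn_s = TypedAttention(dim, rng)
        self.bias_s = SpatialBias(rng)
        self.attn_h = TypedAttention(dim, rng)
        self.ln = {name: LayerNorm(dim) for name in
                   ("t_q", "t_kv", "s_q", "s_kv", "h_q", "h_kv", "mem")}
        self.spatial_cross = spatial_cross

    def _mask(self, neighbors, nq, nk, duplicated):
        if neighbors is None:
            return None
        mask = np.zeros((nq, nk), dtype=bool)
        rows = np.arange(nq)[:, None]
        mask[rows, neighbors] = True
        if duplicated:
            mask[rows, neighbors + nq] = True
        return mask

    def forward(self, d_a, d_m, t_a, t_m, coords, neighbors):
        ln = self.ln
        # temporal: detection queries attend to same-modality memory
        if t_a.shape[0] > 0:
            d_a = d_a + self.attn_t_a(ln["t_q"](d_a), ln["t_kv"](t_a), ln["t_kv"](t_a))
        if t_m.shape[0] > 0:
            d_m = d_m + self.attn_t_m(ln["t_q"](d_m), ln["t_kv"](t_m), ln["t_kv"](t_m))
        # spatial: within-frame attention with relative-position bias
        n = d_a.shape[0]
        if self.spatial_cross:
            kv = concat([ln["s_kv"](d_a), ln["s_kv"](d_m)], axis=0)
            ck = np.concatenate([coords, coords], axis=0)
            mask = self._mask(neighbors, n, 2 * n, duplicated=True)
        else:
            kv, ck, mask = ln["s_kv"](d_a), coords, self._mask(neighbors, n, n, False)
        d_a = d_a + spatial_attention(ln["s_q"](d_a), kv, kv, coords, ck,
                                      self.attn_s, self.bias_s, mask)
        if self.spatial_cross:
            d_m = d_m + spatial_attention(ln["s_q"](d_m), kv, kv, coords, ck,
                                          self.attn_s, self.bias_s, mask)
        else:
            kv_m = ln["s_kv"](d_m)
            d_m = d_m + spatial_attention(ln["s_q"](d_m), kv_m, kv_m, coords, coords,
                                          self.attn_s, self.bias_s, mask)
        # heterogeneous: aggregate across both detection modalities
        blocks = [(ln["h_kv"](d_a), ln["h_kv"](d_a)), (ln["h_kv"](d_m), ln["h_kv"](d_m))]
        d_a = d_a + heterogeneous_attention(ln["h_q"](d_a), blocks, self.attn_h)
        d_m = d_m + heterogeneous_attention(ln["h_q"](d_m), blocks, self.attn_h)
        # memory refresh: memory attends back to refreshed detections
        if t_a.shape[0] > 0:
            t_a = t_a + self.attn_t_a(ln["mem"](t_a), ln["t_kv"](d_a), ln["t_kv"](d_a))
        if t_m.shape[0] > 0:
            t_m = t_m + self.attn_t_m(ln["mem"](t_m), ln["t_kv"](d_m), ln["t_kv"](d_m))
        return d_a, d_m, t_a, t_m


class GraphEncoder(Module):
    """``depth`` rounds of typed attention over the heterogeneous graph."""

    def __init__(self, dim: int, depth: int, rng: np.random.Generator,
                 spatial_cross: bool = True):
        self.rounds = [_Round(dim, rng, spatial_cross) for _ in range(depth)]

    def forward(self, graph: HeteroGraph, depth: int | None = None) -> FusedQueries:
        d_a, d_m = graph.d_a.queries, graph.d_m.queries
        t_a, t_m = graph.t_a, graph.t_m
        rounds = self.rounds if depth is None else self.rounds[:depth]
        for rnd in rounds:
            d_a, d_m, t_a, t_m = rnd(d_a, d_m, t_a, t_m, graph.d_a.coords,
                                     graph.neighbors)
        return FusedQueries(d_a=d_a, d_m=d_m, t_a=t_a, t_m=t_m,
                            coords=graph.d_a.coords)


class DeformableDecoder(Module):
    """Multi-head deformable sampling of a feature grid at reference points.

    Per head, features are bilinearly sampled at reference points plus
    learned offsets, combined with per-point softmax weights (summing to 1
    per head) and a per-head linear map.  Offset and weight layers are
    zero-initialised so training starts at plain uniform sampling.
    """

    def __init__(self, hidden: int, rng: np.random.Generator, heads: int = 8,
                 points: int = 4):
        self.heads, self.points, self.hidden = heads, points, hidden
        self.offset = Linear(hidden, heads * points * 2, rng, zero_init=True)
        self.weight = Linear(hidden, heads * points, rng, zero_init=True)
        self.head_proj = [Linear(hidden, hidden, rng) for _ in range(heads)]

    def forward(self, queries, feat_grid, ref_points) -> Tensor:
        """queries: (Nt, h); feat_grid: (H, W, h); ref_points: (Nt, 2) in [0, 1]."""
        queries = as_tensor(queries)
        feat_grid = as_tensor(feat_grid)
        nt = queries.shape[0]
        if nt == 0:
            return Tensor(np.zeros((0, self.hidden)))
        H, W, _ = feat_grid.shape
        ref = np.asarray(ref_points, float) * np.array([W - 1.0, H - 1.0])
        offs = self.offset(queries).reshape(nt, self.heads, self.points, 2)
        logits = self.weight(queries).reshape(nt, self.heads, self.points)
        amq = logits.softmax(axis=-1)
        out = None
        for m in range(self.heads):
            coords = offs[:, m].reshape(nt * self.points, 2) + np.repeat(ref, self.points, axis=0)
            samp = grid_sample(feat_grid, coords).reshape(nt, self.points, self.hidden)
            w = amq[:, m].reshape(nt, self.points, 1)
            pooled = (samp * w).sum(axis=1)
            term = self.head_proj[m](pooled)
            out = term if out is None else out + term
        return out
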