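"""Heterogeneous-graph construction, typed attention, encoding and
deformable decoding, checked against dense brute-force oracles."""

import numpy as np
import pytest

from hgtrack.autodiff import Tensor
from hgtrack.backbone import QueryMatrix
from hgtrack.mhgn import (DeformableDecoder, GraphEncoder, SpatialBias,
                          TypedAttention, build_graph, heterogeneous_attention,
                          spatial_attention, temporal_attention)


def make_queries(rng, n=4, h=8, modality="appearance", grid_w=2):
    ys, xs = np.divmod(np.arange(n), grid_w)
    return QueryMatrix(queries=Tensor(rng.standard_normal((n, h))),
                       modality=modality, stage=0,
                       coords=np.column_stack([xs, ys]).astype(float))


def dense_attention_oracle(Q, K, V, wq, wk, wv, bias=None):
    """Straight-line softmax(QWq (KWk)^T / sqrt(d)) VWv with numpy."""
    q, k, v = Q @ wq, K @ wk, V @ wv
    logits = q @ k.T / np.sqrt(q.shape[1])
    if bias is not None:
        logits = logits + bias
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    attn = e / e.sum(axis=1, keepdims=True)
    return attn @ v


# ----------------------------------------------------------------------
# build_graph
# ----------------------------------------------------------------------

def test_first_frame_zero_memory_is_valid(rng):
    g = build_graph(make_queries(rng), make_queries(rng, modality="motion"),
                    None, None)
    assert g.t_a.shape == (0, 8)
    assert g.n_detection_tokens == 4


def test_cross_modal_colocation_pairing(rng):
    d_a = make_queries(rng, n=6, grid_w=3)
    d_m = make_queries(rng, n=6, modality="motion", grid_w=3)
    g = build_graph(d_a, d_m, None, None)
    # streams are pixel-aligned: one co-located partner per token
    np.testing.assert_array_equal(g.d_a.coords, g.d_m.coords)


def test_empty_queries_rejected(rng):
    empty = QueryMatrix(queries=Tensor(np.zeros((0, 8))), modality="appearance",
                        stage=0, coords=np.zeros((0, 2)))
    with pytest.raises(ValueError):
        build_graph(empty, empty, None, None)


def test_width_mismatch_rejected(rng):
    d_a = make_queries(rng, h=8)
    d_m = make_queries(rng, h=8, modality="motion")
    with pytest.raises(ValueError):
        build_graph(d_a, d_m, np.zeros((2, 6)), np.zeros((2, 8)))


def test_knn_neighbors_above_dense_limit(rng):
    n = 100
    d_a = make_queries(rng, n=n, grid_w=10)
    d_m = make_queries(rng, n=n, modality="motion", grid_w=10)
    g = build_graph(d_a, d_m, None, None, k_spatial=8)
    assert g.neighbors is not None and g.neighbors.shape == (n, 8)
    # each token is its own nearest neighbour
    assert (g.neighbors[:, 0] == np.arange(n)).all()


# ----------------------------------------------------------------------
# attention operators
# ----------------------------------------------------------------------

def test_single_key_gets_weight_one(rng):
    attn = TypedAttention(8, np.random.default_rng(0))
    w = attn.attention_weights(rng.standard_normal((3, 8)),
                               rng.standard_normal((1, 8)))
    np.testing.assert_allclose(w, 1.0, atol=1e-12)


def test_identical_keys_uniform_weights(rng):
    attn = TypedAttention(8, np.random.default_rng(0))
    key = rng.standard_normal(8)
    w = attn.attention_weights(rng.standard_normal((2, 8)),
                               np.tile(key, (5, 1)))
    np.testing.assert_allclose(w, 0.2, atol=1e-12)


def test_rows_sum_to_one(rng):
    attn = TypedAttention(8, np.random.default_rng(0), heads=2)
    w = attn.attention_weights(rng.standard_normal((4, 8)) * 5,
                               rng.standard_normal((6, 8)) * 5)
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


def test_temporal_attention_matches_dense_oracle(rng):
    attn = TypedAttention(4, np.random.default_rng(1))
    Q = rng.standard_normal((2, 4))
    K = rng.standard_normal((3, 4))
    V = rng.standard_normal((3, 4))
    out = temporal_attention(Q, K, V, attn)
    want = dense_attention_oracle(
        Q + 0.0, K, V, attn.wq.w.data, attn.wk.w.data, attn.wv.w.data)
    # oracle omits biases; zero them in the module for the comparison
    for lin in (attn.wq, attn.wk, attn.wv):
        assert np.all(lin.b.data == 0.0)
    np.testing.assert_allclose(out.data, want, atol=1e-6)


def test_spatial_attention_reduces_to_temporal_when_bias_zero(rng):
    g = np.random.default_rng(2)
    attn = TypedAttention(4, g)
    bias = SpatialBias(g)
    bias.net.fc2.w.data[:] = 0.0
    bias.net.fc2.b.data[:] = 0.0
    Q = rng.standard_normal((3, 4))
    coords = rng.random((3, 2)) * 4
    out_s = spatial_attention(Q, Q, Q, coords, coords, attn, bias)
    out_t = temporal_attention(Q, Q, Q, attn)
    np.testing.assert_allclose(out_s.data, out_t.data, atol=1e-9)


def test_large_bias_concentrates_weight(rng):
    attn = TypedAttention(4, np.random.default_rng(3))
    Q = rng.standard_normal((1, 4))
    K = rng.standard_normal((4, 4))
    bias = np.zeros((1, 1, 4))
    bias[..., 2] = 50.0
    w = attn.attention_weights(Q, K, bias=bias)
    assert w[0, 0, 2] > 1.0 - 1e-9


def test_bias_shift_invariance(rng):
    bias = SpatialBias(np.random.default_rng(4))
    cq = rng.random((3, 2)) * 5
    ck = rng.random((4, 2)) * 5
    shift = np.array([17.0, -6.0])
    np.testing.assert_allclose(bias(cq, ck).data,
                               bias(cq + shift, ck + shift).data, atol=1e-12)


def test_heterogeneous_attention_sum(rng):
    attn = TypedAttention(4, np.random.default_rng(5))
    Q = rng.standard_normal((2, 4))
    K = rng.standard_normal((3, 4))
    V = rng.standard_normal((3, 4))
    # both modalities identical -> exactly 2x the single-modality output
    out2 = heterogeneous_attention(Q, [(K, V), (K, V)], attn)
    out1 = heterogeneous_attention(Q, [(K, V)], attn)
    np.testing.assert_allclose(out2.data, 2 * out1.data, atol=1e-9)
    # zero value blocks -> zero output
    z = heterogeneous_attention(Q, [(K, np.zeros((3, 4))), (K, np.zeros((3, 4)))], attn)
    np.testing.assert_allclose(z.data, 0.0, atol=1e-12)


def test_heterogeneous_matches_dense_oracle(rng):
    attn = TypedAttention(4, np.random.default_rng(6))
    Q = rng.standard_normal((2, 4))
    Ka, Va = rng.standard_normal((2, 4)), rng.standard_normal((2, 4))
    Km, Vm = rng.standard_normal((2, 4)), rng.standard_normal((2, 4))
    out = heterogeneous_attention(Q, [(Ka, Va), (Km, Vm)], attn)
    want = sum(dense_attention_oracle(Q, K, V, attn.wq.w.data, attn.wk.w.data,
                                      attn.wv.w.data)
               for K, V in [(Ka, Va), (Km, Vm)])
    np.testing.assert_allclose(out.data, want, atol=1e-6)


# ----------------------------------------------------------------------
# encoder
# ----------------------------------------------------------------------

def test_depth_zero_is_identity(rng):
    enc = GraphEncoder(8, 2, np.random.default_rng(7))
    g = build_graph(make_queries(rng), make_queries(rng, modality="motion"),
                    rng.standard_normal((2, 8)), rng.standard_normal((2, 8)))
    out = enc(g, depth=0)
    np.testing.assert_array_equal(out.d_a.data, g.d_a.queries.data)
    np.testing.assert_array_equal(out.t_m.data, g.t_m.data)


def test_shapes_preserved_any_depth(rng):
    enc = GraphEncoder(8, 3, np.random.default_rng(8))
    g = build_graph(make_queries(rng, n=6, grid_w=3),
                    make_queries(rng, n=6, modality="motion", grid_w=3),
                    rng.standard_normal((2, 8)), rng.standard_normal((2, 8)))
    out = enc(g)
    assert out.d_a.shape == (6, 8) and out.d_m.shape == (6, 8)
    assert out.t_a.shape == (2, 8) and out.t_m.shape == (2, 8)
    assert np.all(np.isfinite(out.d_a.data))


def test_one_round_equals_manual_composition(rng):
    enc = GraphEncoder(8, 1, np.random.default_rng(9))
    rnd = enc.rounds[0]
    d_a = make_queries(rng, n=3, grid_w=3)
    d_m = make_queries(rng, n=3, modality="motion", grid_w=3)
    t_a = rng.standard_normal((2, 8))
    t_m = rng.standard_normal((2, 8))
    g = build_graph(d_a, d_m, t_a, t_m)
    out = enc(g)
    # manual composition of the three attention ops with the same params
    ln = rnd.ln
    da, dm = d_a.queries, d_m.queries
    ta, tm = Tensor(t_a), Tensor(t_m)
    da = da + rnd.attn_t_a(ln["t_q"](da), ln["t_kv"](ta), ln["t_kv"](ta))
    dm = dm + rnd.attn_t_m(ln["t_q"](dm), ln["t_kv"](tm), ln["t_kv"](tm))
    from hgtrack.autodiff import concat
    kv = concat([ln["s_kv"](da), ln["s_kv"](dm)], axis=0)
    ck = np.concatenate([d_a.coords, d_a.coords], axis=0)
    da2 = da + spatial_attention(ln["s_q"](da), kv, kv, d_a.coords, ck,
                                 rnd.attn_s, rnd.bias_s)
    dm2 = dm + spatial_attention(ln["s_q"](dm), kv, kv, d_a.coords, ck,
                                 rnd.attn_s, rnd.bias_s)
    blocks = [(ln["h_kv"](da2), ln["h_kv"](da2)), (ln["h_kv"](dm2), ln["h_kv"](dm2))]
    da3 = da2 + heterogeneous_attention(ln["h_q"](da2), blocks, rnd.attn_h)
    dm3 = dm2 + heterogeneous_attention(ln["h_q"](dm2), blocks, rnd.attn_h)
    np.testing.assert_allclose(out.d_a.data, da3.data, atol=1e-9)
    np.testing.assert_allclose(out.d_m.data, dm3.data, atol=1e-9)


def test_permutation_equivariance(rng):
    enc = GraphEncoder(8, 1, np.random.default_rng(10))
    d_a = make_queries(rng, n=6, grid_w=3)
    d_m = make_queries(rng, n=6, modality="motion", grid_w=3)
    t_a = rng.standard_normal((2, 8))
    t_m = rng.standard_normal((2, 8))
    out = enc(build_graph(d_a, d_m, t_a, t_m))
    perm = np.random.default_rng(0).permutation(6)
    d_a_p = QueryMatrix(Tensor(d_a.queries.data[perm]), "appearance", 0,
                        d_a.coords[perm])
    d_m_p = QueryMatrix(Tensor(d_m.queries.data[perm]), "motion", 0,
                        d_m.coords[perm])
    out_p = enc(build_graph(d_a_p, d_m_p, t_a, t_m))
    np.testing.assert_allclose(out_p.d_a.data, out.d_a.data[perm], atol=1e-9)
    np.testing.assert_allclose(out_p.d_m.data, out.d_m.data[perm], atol=1e-9)


def test_zero_memory_contributes_zero_temporal_update(rng):
    enc = GraphEncoder(8, 1, np.random.default_rng(11))
    rnd = enc.rounds[0]
    d = Tensor(rng.standard_normal((4, 8)))
    t = Tensor(np.zeros((2, 8)))
    assert np.all(rnd.attn_t_a.wv.b.data == 0.0)
    out = rnd.attn_t_a(rnd.ln["t_q"](d), rnd.ln["t_kv"](t), rnd.ln["t_kv"](t))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_gradient_flow_smoke(rng):
    enc = GraphEncoder(8, 1, np.random.default_rng(12))
    g = build_graph(make_queries(rng, n=4), make_queries(rng, n=4, modality="motion"),
                    rng.standard_normal((2, 8)), rng.standard_normal((2, 8)))
    out = enc(g)
    loss = (out.d_a ** 2).sum() + (out.d_m ** 2).sum() \
        + (out.t_a ** 2).sum() + (out.t_m ** 2).sum()
    loss.backward()
    for p in enc.parameters():
        assert p.grad is not None
        assert np.any(p.grad != 0.0), "parameter received no gradient"


# ----------------------------------------------------------------------
# deformable decoding
# ----------------------------------------------------------------------

def naive_bilinear(grid, x, y):
    H, W, _ = grid.shape
    x = min(max(x, 0.0), W - 1.0)
    y = min(max(y, 0.0), H - 1.0)
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x0, y0 = min(x0, W - 2), min(y0, H - 2)
    fx, fy = x - x0, y - y0
    return ((1 - fx) * (1 - fy) * grid[y0, x0] + fx * (1 - fy) * grid[y0, x0 + 1]
            + (1 - fx) * fy * grid[y0 + 1, x0] + fx * fy * grid[y0 + 1, x0 + 1])


def identity_decoder(hidden, heads=1, points=1):
    dec = DeformableDecoder(hidden, np.random.default_rng(0), heads, points)
    for lin in dec.head_proj:
        lin.w.data[:] = np.eye(hidden) / heads
        lin.b.data[:] = 0.0
    return dec


def test_zero_offset_single_head_equals_plain_sampling(rng):
    grid = Tensor(rng.standard_normal((5, 7, 6)))
    dec = identity_decoder(6)
    q = Tensor(rng.standard_normal((3, 6)))
    refs = rng.random((3, 2))
    out = dec(q, grid, refs)
    for i, (rx, ry) in enumerate(refs):
        want = naive_bilinear(grid.data, rx * 6.0, ry * 4.0)
        np.testing.assert_allclose(out.data[i], want, atol=1e-9)


def test_reference_on_grid_node_is_exact(rng):
    grid = Tensor(rng.standard_normal((4, 4, 5)))
    dec = identity_decoder(5)
    refs = np.array([[1.0 / 3.0, 2.0 / 3.0]])   # node (x=1, y=2) on a 4x4 grid
    out = dec(Tensor(rng.standard_normal((1, 5))), grid, refs)
    np.testing.assert_allclose(out.data[0], grid.data[2, 1], atol=1e-12)


def test_random_grids_match_naive_oracle(rng):
    for trial in range(50):
        H, W, C = rng.integers(2, 7), rng.integers(2, 7), 4
        grid = Tensor(rng.standard_normal((H, W, C)))
        dec = identity_decoder(C)
        refs = rng.random((2, 2))
        out = dec(Tensor(rng.standard_normal((2, C))), grid, refs)
        for i in range(2):
            want = naive_bilinear(grid.data, refs[i, 0] * (W - 1),
                                  refs[i, 1] * (H - 1))
            np.testing.assert_allclose(out.data[i], want, atol=1e-6)


def test_multihead_weights_sum_to_one(rng):
    dec = DeformableDecoder(6, np.random.default_rng(1), heads=8, points=4)
    q = Tensor(rng.standard_normal((3, 6)))
    logits = dec.weight(q).data.reshape(3, 8, 4)
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    amq = e / e.sum(axis=-1, keepdims=True)
    np.testing.assert_allclose(amq.sum(axis=-1), 1.0, atol=1e-12)


def test_empty_track_set(rng):
    dec = DeformableDecoder(6, np.random.default_rng(2))
    out = dec(Tensor(np.zeros((0, 6))), Tensor(rng.standard_normal((4, 4, 6))),
              np.zeros((0, 2)))
    assert out.shape == (0, 6)
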