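"""Neural-network layers, optimizer and schedules on top of :mod:`hgtrack.autodiff`."""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Parameter, Tensor, as_tensor

__all__ = [
    "Module", "Linear", "Conv2d", "LayerNorm", "MLP",
    "conv2d", "grid_sample", "AdamW", "cosine_warmup_lr",
]


# ----------------------------------------------------------------------
# functional primitives
# ----------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on a single image.

    x: (C_in, H, W); w: (C_out, C_in, kh, kw); b: (C_out,).
    Zero padding, integer stride.  Returns (C_out, Ho, Wo).
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, H, W = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin2}")
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    # win: (C_in, Ho, Wo, kh, kw) -> cols (C_in*kh*kw, Ho*Wo)
    cols = win.transpose(0, 3, 4, 1, 2).reshape(cin * kh * kw, Ho * Wo)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = (wmat @ cols).reshape(cout, Ho, Wo)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        out_data = out_data + b.data[:, None, None]
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        gmat = g.reshape(cout, Ho * Wo)
        if w.requires_grad:
            w.grad += (gmat @ cols.T).reshape(w.data.shape)
        if b is not None and b.requires_grad:
            b.grad += g.sum(axis=(1, 2))
        if x.requires_grad:
            dcols = (wmat.T @ gmat).reshape(cin, kh, kw, Ho, Wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += dcols[:, i, j]
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding]
            x.grad += dxp

    out._backward = bwd
    return out


def pad2d_br(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the bottom/right of a (C, H, W) tensor."""
    x = as_tensor(x)
    if pad_h == 0 and pad_w == 0:
        return x
    _, H, W = x.data.shape
    out = Tensor(np.pad(x.data, ((0, 0), (0, pad_h), (0, pad_w))), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.grad += g[:, :H, :W]

    out._backward = bwd
    return out


def grid_sample(feat: Tensor, coords: Tensor) -> Tensor:
    """Bilinear sampling of ``feat`` (H, W, C) at ``coords`` (P, 2) = (x, y) pixels.

    Coordinates clamp to the border (gradient w.r.t. a clamped coordinate is 0).
    Returns (P, C).
    """
    feat, coords = as_tensor(feat), as_tensor(coords)
    H, W, C = feat.data.shape
    x = np.clip(coords.data[:, 0], 0.0, W - 1.0)
    y = np.clip(coords.data[:, 1], 0.0, H - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, W - 2) if W > 1 else np.zeros_like(x, dtype=int)
    y0 = np.clip(np.floor(y).astype(int), 0, H - 2) if H > 1 else np.zeros_like(y, dtype=int)
    x1, y1 = x0 + (1 if W > 1 else 0), y0 + (1 if H > 1 else 0)
    fx, fy = x - x0, y - y0
    w00 = (1 - fx) * (1 - fy)
    w01 = fx * (1 - fy)
    w10 = (1 - fx) * fy
    w11 = fx * fy
    f = feat.data
    out_data = (w00[:, None] * f[y0, x0] + w01[:, None] * f[y0, x1]
                + w10[:, None] * f[y1, x0] + w11[:, None] * f[y1, x1])
    out = Tensor(out_data, parents=(feat, coords))

    def bwd(g):
        if feat.requires_grad:
            np.add.at(feat.grad, (y0, x0), g * w00[:, None])
            np.add.at(feat.grad, (y0, x1), g * w01[:, None])
            np.add.at(feat.grad, (y1, x0), g * w10[:, None])
            np.add.at(feat.grad, (y1, x1), g * w11[:, None])
        if coords.requires_grad:
            dfdx = ((1 - fy)[:, None] * (f[y0, x1] - f[y0, x0])
                    + fy[:, None] * (f[y1, x1] - f[y1, x0]))
            dfdy = ((1 - fx)[:, None] * (f[y1, x0] - f[y0, x0])
                    + fx[:, None] * (f[y1, x1] - f[y0, x1]))
            inx = (coords.data[:, 0] > 0) & (coords.data[:, 0] < W - 1)
            iny = (coords.data[:, 1] > 0) & (coords.data[:, 1] < H - 1)
            coords.grad[:, 0] += (g * dfdx).sum(axis=1) * inx
            coords.grad[:, 1] += (g * dfdy).sum(axis=1) * iny

    out._backward = bwd
    return out


# ----------------------------------------------------------------------
# modules
# ----------------------------------------------------------------------

class Module:
    """Tiny module base: parameter discovery by attribute walk."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x) @ self.w + self.b


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, zero_init: bool = False):
        fan_in = cin * k * k
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(cout))
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with ReLU."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator,
                 zero_last: bool = False):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng, zero_init=zero_last)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


# ----------------------------------------------------------------------
# optimisation
# ----------------------------------------------------------------------

class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def cosine_warmup_lr(step: int, peak_lr: float, warmup_steps: int, total_steps: int) -> float:
    """Linear warmup to ``peak_lr`` then cosine annealing to zero.

    Step 0 after warmup (i.e. step == warmup_steps) returns exactly ``peak_lr``.
    """
    if warmup_steps > 0 and step < warmup_steps:
        return peak_lr * (step + 1) / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    frac = min((step - warmup_steps) / span, 1.0)
    return peak_lr * 0.5 * (1.0 + math.cos(math.pi * frac))
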