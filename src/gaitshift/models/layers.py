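"""NumPy neural-network layers with explicit forward/backward passes.

Everything operates on [batch x time x channels] float arrays. The layer
set is exactly what the A1-A5 architectures need: length-preserving Conv1D,
ReLU, dropout, layer normalisation (with or without learned affine),
multi-head self-attention over time (parameter-free or with learned
Q/K/V/output projections, always with a residual connection), a
single-layer bidirectional LSTM that emits the concatenated final hidden
states of both directions, global average pooling, and an affine head.
Conventions that pin down trainable-parameter counts: convs use kernel 3,
stride 1, same padding and a bias; the LSTM carries two bias vectors per
direction; attention uses 4 heads by reshaping the 64-dim features.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "ReLU",
    "Dropout",
    "LayerNorm",
    "SelfAttention",
    "BiLSTMLast",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Temporal convolution, stride 1, zero 'same' padding, with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel * in_ch))
        self.W = Param(rng.normal(0.0, std, size=(kernel, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # xw[b, t, c, j] == xp[b, t + j, c]
        xw = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        self._xw = xw
        self._T = x.shape[1]
        return np.einsum("btcj,jco->bto", xw, self.W.value) + self.b.value

    def backward(self, gy):
        k, T = self.kernel, self._T
        pad = k // 2
        self.W.grad += np.einsum("btcj,bto->jco", self._xw, gy)
        self.b.grad += gy.sum(axis=(0, 1))
        gxp = np.zeros((gy.shape[0], T + 2 * pad, self.in_ch))
        for j in range(k):
            gxp[:, j:j + T, :] += gy @ self.W.value[j].T
        return gxp[:, pad:pad + T, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float = 0.2):
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class LayerNorm(Layer):
    """Normalisation over the channel axis; optional learned affine."""

    def __init__(self, dim: int, affine: bool = False, eps: float = 1e-5):
        self.affine = affine
        self.eps = eps
        if affine:
            self.g = Param(np.ones(dim))
            self.b = Param(np.zeros(dim))

    def params(self):
        return [self.g, self.b] if self.affine else []

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        if self.affine:
            return self.g.value * self._xhat + self.b.value
        return self._xhat

    def backward(self, gy):
        xhat = self._xhat
        if self.affine:
            self.g.grad += (gy * xhat).sum(axis=tuple(range(gy.ndim - 1)))
            self.b.grad += gy.sum(axis=tuple(range(gy.ndim - 1)))
            gy = gy * self.g.value
        m1 = gy.mean(axis=-1, keepdims=True)
        m2 = (gy * xhat).mean(axis=-1, keepdims=True)
        return self._inv * (gy - m1 - xhat * m2)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_dim + out_dim))
        self.W = Param(rng.normal(0.0, std, size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = gy.reshape(-1, gy.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return gy @ self.W.value.T


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SelfAttention(Layer):
    """Multi-head scaled dot-product self-attention over time + residual.

    ``projected=False``: queries, keys and values are the input features
    reshaped into heads — no trainable parameters at all. ``projected=True``
    adds learned Q/K/V and output projections (dim x dim each, with bias).
    Output is ``x + attention(x)``.
    """

    def __init__(self, dim: int, heads: int = 4, projected: bool = False,
                 rng: np.random.Generator | None = None):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.projected = dim, heads, projected
        self.dh = dim // heads
        if projected:
            rng = rng or np.random.default_rng(0)
            self.Wq = Linear(dim, dim, rng)
            self.Wk = Linear(dim, dim, rng)
            self.Wv = Linear(dim, dim, rng)
            self.Wo = Linear(dim, dim, rng)

    def params(self):
        if not self.projected:
            return []
        return (self.Wq.params() + self.Wk.params()
                + self.Wv.params() + self.Wo.params())

    def _to_heads(self, x):
        B, T, D = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _from_heads(self, xh):
        B, H, T, dh = xh.shape
        return xh.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, x, train=False):
        self._x = x
        if self.projected:
            q, k, v = self.Wq.forward(x), self.Wk.forward(x), self.Wv.forward(x)
        else:
            q = k = v = x
        qh, kh, vh = self._to_heads(q), self._to_heads(k), self._to_heads(v)
        scale = 1.0 / np.sqrt(self.dh)
        S = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale
        A = _softmax_last(S)
        Yh = np.matmul(A, vh)
        self._cache = (qh, kh, vh, A, scale)
        Y = self._from_heads(Yh)
        if self.projected:
            self._Y = Y
            Y = self.Wo.forward(Y)
        return x + Y

    def backward(self, gy):
        qh, kh, vh, A, scale = self._cache
        g_out = gy
        if self.projected:
            g_out = self.Wo.backward(gy)
        gYh = self._to_heads(g_out)
        gA = np.matmul(gYh, vh.transpose(0, 1, 3, 2))
        gvh = np.matmul(A.transpose(0, 1, 3, 2), gYh)
        gS = A * (gA - (gA * A).sum(axis=-1, keepdims=True))
        gqh = np.matmul(gS, kh) * scale
        gkh = np.matmul(gS.transpose(0, 1, 3, 2), qh) * scale
        gq = self._from_heads(gqh)
        gk = self._from_heads(gkh)
        gv = self._from_heads(gvh)
        if self.projected:
            gx = (self.Wq.backward(gq) + self.Wk.backward(gk)
                  + self.Wv.backward(gv))
        else:
            gx = gq + gk + gv
        return gy + gx  # residual path


class BiLSTMLast(Layer):
    """One-layer bidirectional LSTM returning [h_fwd_final, h_bwd_final].

    Each direction holds W_ih [in x 4h], W_hh [h x 4h] and two bias vectors
    (4h each), i.e. 4h(in + h) + 8h parameters per direction. Gate order is
    input, forget, cell, output.
    """

    def __init__(self, in_dim: int, hidden: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.hidden = in_dim, hidden
        bound = 1.0 / np.sqrt(hidden)
        def u(*shape):
            return Param(rng.uniform(-bound, bound, size=shape))
        self.dirs = []
        for _ in range(2):
            self.dirs.append({
                "W_ih": u(in_dim, 4 * hidden), "W_hh": u(hidden, 4 * hidden),
                "b_ih": u(4 * hidden), "b_hh": u(4 * hidden),
            })

    def params(self):
        out = []
        for d in self.dirs:
            out += [d["W_ih"], d["W_hh"], d["b_ih"], d["b_hh"]]
        return out

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    def forward(self, x, train=False):
        # Both directions run through one time loop: the backward direction
        # sees the time-reversed sequence, stacked on a leading dir axis.
        self._x = x
        B, T, _ = x.shape
        h = self.hidden
        xs = np.stack([x, x[:, ::-1, :]])  # [2, B, T, in]
        W_ih = np.stack([d["W_ih"].value for d in self.dirs])
        W_hh = np.stack([d["W_hh"].value for d in self.dirs])
        bias = np.stack([d["b_ih"].value + d["b_hh"].value for d in self.dirs])
        xz = xs @ W_ih[:, None] + bias[:, None, None, :]
        ht = np.zeros((2, B, h))
        ct = np.zeros((2, B, h))
        cache = []
        for t in range(T):
            z = xz[:, :, t, :] + ht @ W_hh
            i = self._sigmoid(z[..., :h])
            f = self._sigmoid(z[..., h:2 * h])
            g = np.tanh(z[..., 2 * h:3 * h])
            o = self._sigmoid(z[..., 3 * h:])
            c_prev, h_prev = ct, ht
            ct = f * c_prev + i * g
            tc = np.tanh(ct)
            ht = o * tc
            cache.append((h_prev, c_prev, i, f, g, o, tc))
        self._cache = cache
        self._xs = xs
        return np.concatenate([ht[0], ht[1]], axis=1)

    def backward(self, gy):
        B, T, _ = self._x.shape
        h = self.hidden
        W_ih = np.stack([d["W_ih"].value for d in self.dirs])
        W_hh = np.stack([d["W_hh"].value for d in self.dirs])
        gW_ih = np.zeros_like(W_ih)
        gW_hh = np.zeros_like(W_hh)
        gb = np.zeros((2, 4 * h))
        gxs = np.zeros_like(self._xs)
        gh = np.stack([gy[:, :h], gy[:, h:]])
        gc = np.zeros((2, B, h))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            go = gh * tc
            gc = gc + gh * o * (1 - tc * tc)
            gi = gc * g
            gg = gc * i
            gf = gc * c_prev
            gc = gc * f
            gz = np.concatenate([
                gi * i * (1 - i), gf * f * (1 - f),
                gg * (1 - g * g), go * o * (1 - o)], axis=2)
            gW_ih += self._xs[:, :, t, :].transpose(0, 2, 1) @ gz
            gW_hh += h_prev.transpose(0, 2, 1) @ gz
            gb += gz.sum(axis=1)
            gxs[:, :, t, :] = gz @ W_ih.transpose(0, 2, 1)
            gh = gz @ W_hh.transpose(0, 2, 1)
        for d_idx, d in enumerate(self.dirs):
            d["W_ih"].grad += gW_ih[d_idx]
            d["W_hh"].grad += gW_hh[d_idx]
            d["b_ih"].grad += gb[d_idx]
            d["b_hh"].grad += gb[d_idx]
        return gxs[0] + gxs[1][:, ::-1, :]


class GlobalAvgPool(Layer):
    """Mean over the time axis: [B x T x C] -> [B x C]."""

    def forward(self, x, train=False):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy):
        return np.repeat(gy[:, None, :], self._T, axis=1) / self._T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng


def softmax(scores: np.ndarray) -> np.ndarray:
    return _softmax_last(scores)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    p = _softmax_last(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n
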