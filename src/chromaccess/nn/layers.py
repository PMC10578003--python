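"""Minimal trainable tensor layers (numpy, manual backprop).

Every layer keeps its forward cache on the instance, so a layer object is
single-use-at-a-time: call ``forward`` then ``backward`` before the next
``forward``.  Parameters and their gradients live in ``params`` / ``grads``
dicts keyed by short names; an optimizer walks ``iter_params()``.

All sequence layers use channels-last ``(batch, length, channels)`` layout:
convolution lowers to im2col + one GEMM, pooling to an elementwise
``maximum`` over stride slices, and the attention block consumes the conv
output directly with no transposition.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: a differentiable module with named parameters."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def iter_params(self):
        for k in self.params:
            yield self, k


class Conv1d(Layer):
    """Same-padded 1-D convolution over (B, L, C), via im2col + GEMM."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.needs_input_grad = needs_input_grad
        fan_in = in_ch * kernel
        # He initialisation (ReLU follows every conv in this architecture)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        B, L, C = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # windows over length: (B, L, C, k) -> (B*L, k*C) with k-major order
        cols = sliding_window_view(xp, k, axis=1)          # (B, L, C, k)
        cols = cols.transpose(0, 1, 3, 2).reshape(B * L, k * C)
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(B, L, self.out_ch)

    def backward(self, dout):
        B, L, C = self._xshape
        k, pad = self.kernel, self.kernel // 2
        d = dout.reshape(B * L, self.out_ch)
        self.grads["W"][...] = self._cols.T @ d
        self.grads["b"][...] = d.sum(axis=0)
        if not self.needs_input_grad:  # first layer: input is data
            return None
        dcols = (d @ self.params["W"].T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + 2 * pad, C), dtype=dcols.dtype)
        for j in range(k):  # k is small; contiguous scatter-add per tap
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, pad : pad + L, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, train, (B, L, C) = self._cache
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 1))
        self.grads["beta"][...] = dout.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not train:
            return dout * (g * inv)
        n = B * L
        dxhat = dout * g
        term = dxhat - dxhat.mean(axis=(0, 1), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 1), keepdims=True) / n
        return term * inv


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling over length with floor semantics."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        B, L, C = x.shape
        p = self.pool
        Lp = L // p
        if p == 1:
            self._winners = None
            return x
        slices = [x[:, j : Lp * p : p, :] for j in range(p)]
        out = slices[0]
        winner = np.zeros(out.shape, dtype=np.int8)
        for j in range(1, p):
            better = slices[j] > out
            out = np.where(better, slices[j], out)
            winner = np.where(better, j, winner)
        self._winners, self._inshape = winner, x.shape
        return out

    def backward(self, dout):
        if self._winners is None:
            return dout
        B, L, C = self._inshape
        p = self.pool
        Lp = L // p
        dx = np.zeros(self._inshape, dtype=dout.dtype)
        for j in range(p):
            dx[:, j : Lp * p : p, :] = np.where(self._winners == j, dout, 0)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu_gain: bool = True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_gain else 1.0) / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def sinusoidal_encoding(n_tokens: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding, added to token embeddings."""
    pos = np.arange(n_tokens)[:, None].astype(np.float64)
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


def _softmax(z):
    # in-place: z is always a freshly computed scores array
    z -= z.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    return z


class MultiHeadAttention(Layer):
    """Scaled dot-product self-attention over (batch, tokens, dim)."""

    def __init__(self, dim: int, heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"model dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        scale = np.sqrt(1.0 / dim)  # Xavier-style for linear maps
        self.params = {}
        for name in ("q", "k", "v", "o"):
            self.params["W" + name] = rng.normal(0.0, scale, size=(dim, dim)).astype(np.float32)
            self.params["b" + name] = np.zeros(dim, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.attn_dropout = Dropout(dropout, rng)

    def _split(self, x):  # (B,T,D) -> (B,h,T,dh)
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _join(self, x):  # (B,h,T,dh) -> (B,T,D)
        B, h, T, dh = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(B, T, h * dh)

    def forward(self, x, train=False):
        p = self.params
        q = self._split(x @ p["Wq"] + p["bq"])
        k = self._split(x @ p["Wk"] + p["bk"])
        v = self._split(x @ p["Wv"] + p["bv"])
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / float(np.sqrt(self.dh)))
        attn = _softmax(scores)
        attn_d = self.attn_dropout.forward(attn, train=train)
        ctx = attn_d @ v
        joined = self._join(ctx)
        out = joined @ p["Wo"] + p["bo"]
        self._cache = (x, q, k, v, attn, attn_d, joined)
        return out

    def backward(self, dout):
        p, g = self.params, self.grads
        x, q, k, v, attn, attn_d, joined = self._cache
        B, T, D = x.shape
        g["Wo"][...] = joined.reshape(-1, D).T @ dout.reshape(-1, D)
        g["bo"][...] = dout.sum(axis=(0, 1))
        djoined = dout @ p["Wo"].T
        dctx = self._split(djoined)
        dattn_d = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn_d.transpose(0, 1, 3, 2) @ dctx
        dattn = self.attn_dropout.backward(dattn_d)
        # softmax backward per row
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= 1.0 / float(np.sqrt(self.dh))
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        xf = x.reshape(-1, D)
        for name, dproj in (("q", dq), ("k", dk), ("v", dv)):
            dflat = self._join(dproj).reshape(-1, D)
            g["W" + name][...] = xf.T @ dflat
            g["b" + name][...] = dflat.sum(axis=0)
            dx += (dflat @ p["W" + name].T).reshape(B, T, D)
        return dx
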