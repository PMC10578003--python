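"""Hybrid convolution–attention multi-task accessibility classifier.

Architecture: four shared blocks of (same-padded conv → batch norm → ReLU →
max pool), a fixed sinusoidal positional encoding added to the resulting
token sequence, one shared multi-head self-attention layer, and one
fully connected head per tissue (linear → dropout → ReLU → linear →
sigmoid).  The two heads read the flattened attention output and emit one
accessibility probability each; training minimizes the sum over tissues of
the per-tissue mean binary cross-entropy.

Pooling uses floor semantics, so the 1000-bp input shrinks 1000 → 500 →
250 → 125 → 62 tokens with the default pool size of 2.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import layers as ly


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of the model and its SGD training loop."""

    input_length: int = 1000
    tissues: tuple[str, ...] = ("head", "testis")
    conv_layers: int = 4
    filters_per_layer: tuple[int, ...] = (128, 128, 128, 128)
    kernel_size: int = 7
    pool_size: int = 2
    attention_heads: int = 4
    attention_dropout: float = 0.3
    fc_dropout: float = 0.3
    fc_hidden: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.9
    clip_norm: float = 5.0   # global gradient-norm clip; 0 disables
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for d in (self.attention_dropout, self.fc_dropout):
            if not 0.0 <= d < 1.0:
                raise ValueError("dropout fractions must be in [0, 1)")
        if len(self.filters_per_layer) != self.conv_layers:
            raise ValueError("filters_per_layer must have one entry per conv layer")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    @property
    def n_tokens(self) -> int:
        n = self.input_length
        for _ in range(self.conv_layers):
            n //= self.pool_size
        return n

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters_per_layer"] = list(self.filters_per_layer)
        d["tissues"] = list(self.tissues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["filters_per_layer"] = tuple(d["filters_per_layer"])
        d["tissues"] = tuple(d["tissues"])
        return cls(**d)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AccessibilityNet:
    """The trained predictor: one-hot sequence -> per-tissue P(accessible)."""

    def __init__(self, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.conv_blocks: list[list[ly.Layer]] = []
        in_ch = 4
        for i, f in enumerate(config.filters_per_layer):
            self.conv_blocks.append(
                [
                    ly.Conv1d(in_ch, f, config.kernel_size, rng,
                              needs_input_grad=i > 0),
                    ly.BatchNorm1d(f),
                    ly.ReLU(),
                    ly.MaxPool1d(config.pool_size),
                ]
            )
            in_ch = f
        self.dim = in_ch
        self.pos_enc = ly.sinusoidal_encoding(config.n_tokens, self.dim)
        self.attention = ly.MultiHeadAttention(self.dim, config.attention_heads,
                                               config.attention_dropout, rng)
        flat = config.n_tokens * self.dim
        self.heads: dict[str, list[ly.Layer]] = {}
        for tissue in config.tissues:
            self.heads[tissue] = [
                ly.Linear(flat, config.fc_hidden, rng),
                ly.Dropout(config.fc_dropout, rng),
                ly.ReLU(),
                ly.Linear(config.fc_hidden, 1, rng, relu_gain=False),
            ]

    # ---- plumbing -------------------------------------------------------

    def _all_layers(self):
        for block in self.conv_blocks:
            yield from block
        yield self.attention
        for head in self.heads.values():
            yield from head

    def iter_params(self):
        for layer in self._all_layers():
            yield from layer.iter_params()

    def n_parameters(self) -> int:
        return sum(p.size for layer, k in self.iter_params() for p in [layer.params[k]])

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All trainable parameters plus batch-norm running statistics."""
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in layer.params.items():
                out[f"{i}:{k}"] = v
            if isinstance(layer, ly.BatchNorm1d):
                out[f"{i}:running_mean"] = layer.running_mean
                out[f"{i}:running_var"] = layer.running_var
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        live = self.state_arrays()
        if set(live) != set(state):
            raise ValueError("checkpoint state does not match architecture")
        for k, v in live.items():
            v[...] = state[k]

    # ---- forward / backward --------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, 4, L) float32 one-hot -> (B, n_tissues) pre-sigmoid logits."""
        if x.ndim != 3 or x.shape[1] != 4 or x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected input of shape (B, 4, {self.config.input_length}), got {x.shape}"
            )
        h = np.ascontiguousarray(x.transpose(0, 2, 1))  # channels-last (B, L, 4)
        for block in self.conv_blocks:
            for layer in block:
                h = layer.forward(h, train=train)
        h = h + self.pos_enc[None]  # (B, T, D)
        h = self.attention.forward(h, train=train)
        self._flat_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        outs = []
        self._head_order = list(self.config.tissues)
        for tissue in self._head_order:
            z = flat
            for layer in self.heads[tissue]:
                z = layer.forward(z, train=train)
            outs.append(z[:, 0])
        return np.stack(outs, axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        B = dlogits.shape[0]
        dflat = np.zeros((B, self._flat_shape[1] * self._flat_shape[2]), dtype=np.float32)
        for j, tissue in enumerate(self._head_order):
            d = dlogits[:, j : j + 1].astype(np.float32)
            for layer in reversed(self.heads[tissue]):
                d = layer.backward(d)
            dflat += d
        dh = dflat.reshape(self._flat_shape)
        dh = self.attention.backward(dh)
        for block in reversed(self.conv_blocks):
            for layer in reversed(block):
                dh = layer.backward(dh)

    # ---- inference ------------------------------------------------------

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic inference: (B, 4, L) -> (B, n_tissues) in (0, 1)."""
        single = x.ndim == 2
        if single:
            x = x[None]
        probs = np.empty((x.shape[0], len(self.config.tissues)))
        for i in range(0, x.shape[0], batch_size):
            chunk = np.asarray(x[i : i + batch_size], dtype=np.float32)
            probs[i : i + batch_size] = sigmoid(self.forward_logits(chunk, train=False))
        return probs[0] if single else probs

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k.replace(":", "__"): v for k, v in self.state_arrays().items()}
        np.savez(path, __config__=json.dumps(self.config.to_dict()), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AccessibilityNet":
        with np.load(path, allow_pickle=False) as data:
            config = TrainConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(config)
            state = {
                k.replace("__", ":"): data[k] for k in data.files if k != "__config__"
            }
        model.set_state(state)
        return model


def build_model(config: TrainConfig) -> AccessibilityNet:
    """Construct an untrained model from a config (deterministic in config.seed)."""
    return AccessibilityNet(config)


def bce_loss_and_grad(logits: np.ndarray, labels: np.ndarray):
    """Summed-over-tissues mean binary cross-entropy and its logit gradient.

    Returns (loss, dlogits) where loss = sum_t mean_batch BCE_t, computed
    stably from logits: BCE(z, y) = max(z,0) - z*y + log(1+exp(-|z|)).
    """
    z = logits.astype(np.float64)
    y = labels.astype(np.float64)
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = per.mean(axis=0).sum()
    dlogits = (sigmoid(z) - y) / z.shape[0]
    return loss, dlogits


@dataclasses.dataclass
class _SurrogateConfig:
    tissues: tuple[str, ...]
    input_length: int
    pool_size: int = 0  # marks the model as unsupported by the fast scan


class LinearLogitModel:
    """Additive surrogate model: logit_t(x) = <W_t, x> + b_t.

    Every position contributes independently, so the best single mutation
    under any objective has a closed form.  Used as an independent oracle
    for greedy-search and mutagenesis tests, and handy for worked examples.
    """

    def __init__(self, weights: np.ndarray, bias: np.ndarray,
                 tissues: tuple[str, ...] = ("head", "testis")):
        self.weights = np.asarray(weights, dtype=np.float64)  # (T, 4, L)
        self.bias = np.asarray(bias, dtype=np.float64)        # (T,)
        if self.weights.ndim != 3 or self.weights.shape[0] != len(tissues):
            raise ValueError("weights must be (n_tissues, 4, L)")
        self.config = _SurrogateConfig(tuple(tissues), self.weights.shape[2])

    def logits(self, x: np.ndarray) -> np.ndarray:
        single = x.ndim == 2
        if single:
            x = x[None]
        z = np.einsum("bcl,tcl->bt", x.astype(np.float64), self.weights) + self.bias
        return z[0] if single else z

    def predict(self, x: np.ndarray, batch_size: int = 0) -> np.ndarray:
        return sigmoid(self.logits(x))


def bce_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Summed-over-tissues mean BCE from probabilities (for reporting)."""
    p = np.clip(np.asarray(probs, dtype=np.float64), eps, 1 - eps)
    y = np.asarray(labels, dtype=np.float64)
    per = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(per.mean(axis=0).sum())
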