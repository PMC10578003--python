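"""SGD-with-momentum training loop with patience-based early stopping.

Early stopping monitors the validation loss: if no new strict minimum is
seen for ``patience`` consecutive epochs, training halts and the parameters
from the minimum-validation-loss epoch are restored.  The controller is a
standalone class so it can be exercised against scripted loss sequences.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .model import AccessibilityNet, TrainConfig, bce_loss_and_grad, sigmoid


class EarlyStopper:
    """Tracks the running validation-loss minimum and signals when to stop.

    ``update`` returns True when training should stop, i.e. when the number
    of consecutive epochs without strict improvement reaches ``patience``.
    ``best_epoch`` is the (0-based) epoch of the minimum.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class SGD:
    """Stochastic gradient descent with classical momentum and optional
    global gradient-norm clipping (stabilizes the attention block)."""

    def __init__(self, model: AccessibilityNet, lr: float, momentum: float,
                 clip_norm: float = 0.0):
        self.model, self.lr, self.momentum = model, lr, momentum
        self.clip_norm = clip_norm
        self.velocity = {
            (id(layer), k): np.zeros_like(layer.params[k])
            for layer, k in model.iter_params()
        }

    def step(self):
        scale = 1.0
        if self.clip_norm > 0:
            sq = sum(float(np.vdot(layer.grads[k], layer.grads[k]))
                     for layer, k in self.model.iter_params())
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for layer, k in self.model.iter_params():
            v = self.velocity[(id(layer), k)]
            v *= self.momentum
            v -= (self.lr * scale) * layer.grads[k]
            layer.params[k] += v


def evaluate_loss(model: AccessibilityNet, X: np.ndarray, y: np.ndarray,
                  batch_size: int = 512) -> float:
    """Validation loss in inference mode (dropout off, running BN stats)."""
    total = np.zeros(y.shape[1])
    for i in range(0, X.shape[0], batch_size):
        chunk = np.asarray(X[i : i + batch_size], dtype=np.float32)
        z = model.forward_logits(chunk, train=False)
        zz = z.astype(np.float64)
        yy = y[i : i + batch_size].astype(np.float64)
        per = np.maximum(zz, 0) - zz * yy + np.log1p(np.exp(-np.abs(zz)))
        total += per.sum(axis=0)
    return float((total / X.shape[0]).sum())


def train(model: AccessibilityNet, train_data, val_data,
          config: TrainConfig | None = None, verbose: bool = False):
    """Train in place; returns (model, history DataFrame).

    ``train_data`` / ``val_data`` are (X, y) pairs with X of shape
    (n, 4, L) one-hot (any integer or float dtype) and y of shape
    (n, n_tissues) in {0, 1}.
    """
    config = config or model.config
    Xtr, ytr = train_data
    Xva, yva = val_data
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    opt = SGD(model, config.learning_rate, config.momentum, config.clip_norm)
    stopper = EarlyStopper(config.patience)
    best_state = model.get_state()
    rows = []
    for epoch in range(config.max_epochs):
        t0 = time.time()
        order = rng.permutation(len(Xtr))
        train_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = np.asarray(Xtr[idx], dtype=np.float32)
            yb = ytr[idx]
            logits = model.forward_logits(xb, train=True)
            loss, dlogits = bce_loss_and_grad(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            model.backward(dlogits)
            opt.step()
            train_loss += loss
            n_batches += 1
        train_loss /= max(n_batches, 1)
        val_loss = evaluate_loss(model, Xva, yva)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged: non-finite validation loss at epoch {epoch}")
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
                     "seconds": time.time() - t0})
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.get_state()
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}"
                  f"{'  *' if improved else ''}")
        if stop:
            break
    model.set_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = stopper.best_epoch
    return model, history


def predict(model: AccessibilityNet, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Convenience alias for deterministic inference."""
    return model.predict(x, batch_size=batch_size)
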