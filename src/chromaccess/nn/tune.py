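"""Hyperparameter search with a pluggable suggest/observe engine.

The search engine is deliberately abstract: anything exposing
``suggest(space, rng) -> dict`` and ``observe(params, loss)`` can drive the
search (a TPE-style optimizer would plug in here); the bundled default is
seeded random search.  The objective receives a :class:`TrainConfig` and
returns a validation loss — in the pipeline that objective trains the model
for a fixed small number of epochs.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd

from .model import TrainConfig


class RandomSearch:
    """Uniform random sampling over a {name: list-of-choices} space."""

    def suggest(self, space: dict, rng: np.random.Generator) -> dict:
        return {name: choices[rng.integers(len(choices))] for name, choices in space.items()}

    def observe(self, params: dict, loss: float) -> None:  # stateless engine
        pass


DEFAULT_SEARCH_SPACE = {
    "kernel_size": [5, 7, 9, 11],
    "pool_size": [2],
    "attention_dropout": [0.0, 0.1, 0.3, 0.5],
    "fc_dropout": [0.0, 0.1, 0.3, 0.5],
    "momentum": [0.0, 0.5, 0.9, 0.99],
}


def tune_hyperparameters(
    search_space: dict,
    objective: Callable[[TrainConfig], float],
    base_config: TrainConfig | None = None,
    n_trials: int = 100,
    engine=None,
    seed: int = 0,
):
    """Minimize ``objective`` over configs drawn from ``search_space``.

    Returns (best TrainConfig, trial log DataFrame).  Ties keep the earliest
    trial.  Each trial's sampled parameters override fields of
    ``base_config``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base = base_config or TrainConfig()
    engine = engine or RandomSearch()
    rng = np.random.default_rng(seed)
    rows, configs = [], []
    for trial in range(n_trials):
        params = engine.suggest(search_space, rng)
        config = dataclasses.replace(base, **params)
        loss = float(objective(config))
        engine.observe(params, loss)
        rows.append({"trial": trial, "val_loss": loss, **params})
        configs.append(config)
    log = pd.DataFrame(rows)
    best_idx = int(log["val_loss"].idxmin())
    return configs[best_idx], log
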