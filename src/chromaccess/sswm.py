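"""Greedy in-silico evolution under strong selection, weak mutation.

Each generation, every sequence one substitution away from the current
sequence is scored by the model; the mutation maximizing the selection
objective — a signed sum of per-tissue log-odds, Σ_t w_t·logit(p_t) — is
fixed.  With weights {head:+1} this selects for head accessibility; with
{head:+1, testis:-1} it selects for head-specific accessibility.  The walk
is fully deterministic: ties break to the earliest mutant in enumeration
order (position-major, alternative bases in A<C<G<T order), and by default
the best mutation is applied even when its objective gain is non-positive
(flagged in the trajectory); ``stop_on_no_improvement`` halts instead.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .ism import _mutant_batch, logit

BASE_ORDER = "ACGT"


@dataclasses.dataclass(frozen=True)
class SelectionObjective:
    """Per-tissue selection weights in {-1, 0, +1}."""

    weights: dict[str, int]

    def __post_init__(self):
        if not any(self.weights.values()):
            raise ValueError("objective needs at least one nonzero weight")

    def value(self, probs: np.ndarray, tissues) -> np.ndarray:
        """Σ_t w_t · logit(p_t); probs has tissues along the last axis."""
        w = np.array([self.weights.get(t, 0) for t in tissues], dtype=float)
        return logit(probs) @ w


@dataclasses.dataclass
class Mutation:
    position: int
    from_base: str
    to_base: str


@dataclasses.dataclass
class SSWMTrajectory:
    example_id: str
    objective: SelectionObjective
    generations: pd.DataFrame   # generation,position,from_base,to_base,objective,p_<tissue>...
    final_seq: np.ndarray       # (4, L) one-hot

    def mutations(self) -> set[tuple[int, str]]:
        g = self.generations[self.generations.generation > 0]
        return set(zip(g.position.astype(int), g.to_base))


def enumerate_single_mutants(seq: np.ndarray) -> Iterator[tuple[int, str, str, np.ndarray]]:
    """Yield (position, from_base, to_base, mutant one-hot) for all 3L
    single-substitution neighbours, position-major, bases in A<C<G<T order.

    Sequences with ambiguous (all-zero) columns are rejected.
    """
    seq = np.asarray(seq)
    if (seq.sum(axis=0) == 0).any():
        raise ValueError("sequence contains ambiguous (N) positions")
    ref_base = seq.argmax(axis=0)
    for pos in range(seq.shape[1]):
        for b in range(4):
            if b == ref_base[pos]:
                continue
            mut = seq.copy()
            mut[:, pos] = 0
            mut[b, pos] = 1
            yield pos, BASE_ORDER[ref_base[pos]], BASE_ORDER[b], mut


def sswm_step(model, seq: np.ndarray, objective: SelectionObjective,
              batch_size: int = 768):
    """One greedy step: the argmax mutant over all 3L single mutants.

    Returns (mutation, mutant sequence, new objective value, delta,
    per-tissue probabilities of the chosen mutant).  Uses the incremental
    mutant scan when the model supports it.
    """
    seq = np.asarray(seq, dtype=np.uint8)
    if (seq.sum(axis=0) == 0).any():
        raise ValueError("sequence contains ambiguous (N) positions")
    tissues = model.config.tissues
    from .nn import fastscan
    if isinstance(model, fastscan.AccessibilityNet) and fastscan.supports_fast_scan(model):
        p_ref, p_mut = fastscan.predict_all_single_mutants(model, seq, chunk=batch_size)
        cur = objective.value(p_ref[None], tissues)[0]
        vals = objective.value(p_mut, tissues)
        muts = None
    else:
        cur = objective.value(model.predict(seq)[None], tissues)[0]
        muts = _mutant_batch(seq)  # order matches enumerate_single_mutants
        p_mut = model.predict(muts, batch_size=batch_size)
        vals = objective.value(p_mut, tissues)
    best = int(np.argmax(vals))  # first maximizer = earliest in enumeration order
    ref_base = seq.argmax(axis=0)
    pos = best // 3
    alt_rank = best % 3
    alt_bases = [b for b in range(4) if b != ref_base[pos]]
    to = alt_bases[alt_rank]
    mutation = Mutation(position=pos, from_base=BASE_ORDER[ref_base[pos]],
                        to_base=BASE_ORDER[to])
    if muts is None:
        best_seq = seq.copy()
        best_seq[:, pos] = 0
        best_seq[to, pos] = 1
    else:
        best_seq = muts[best]
    return mutation, best_seq, float(vals[best]), float(vals[best] - cur), p_mut[best]


def evolve(model, seq: np.ndarray, objective: SelectionObjective,
           generations: int = 30, example_id: str = "",
           stop_on_no_improvement: bool = False,
           stop_condition: Callable[[dict], bool] | None = None,
           batch_size: int = 768) -> SSWMTrajectory:
    """Run the greedy walk; records per-generation outputs for all tissues.

    ``stop_condition`` receives each generation's record (with per-tissue
    outputs) and may halt the walk early, e.g. once a threshold is crossed.
    """
    seq = np.asarray(seq, dtype=np.uint8).copy()
    tissues = list(model.config.tissues)
    p = model.predict(seq)
    rows = [{"generation": 0, "position": -1, "from_base": "", "to_base": "",
             "objective": float(objective.value(p[None], tissues)[0]),
             "delta": np.nan, "improved": True,
             **{f"p_{t}": float(p[j]) for j, t in enumerate(tissues)}}]
    if not (stop_condition and stop_condition(rows[-1])):
        for gen in range(1, generations + 1):
            mutation, new_seq, val, delta, p = sswm_step(model, seq, objective,
                                                         batch_size=batch_size)
            if stop_on_no_improvement and delta <= 0:
                break
            seq = new_seq
            rows.append({"generation": gen, "position": mutation.position,
                         "from_base": mutation.from_base, "to_base": mutation.to_base,
                         "objective": val, "delta": delta, "improved": delta > 0,
                         **{f"p_{t}": float(p[j]) for j, t in enumerate(tissues)}})
            if stop_condition and stop_condition(rows[-1]):
                break
    return SSWMTrajectory(example_id=example_id, objective=objective,
                          generations=pd.DataFrame(rows), final_seq=seq)


def path_overlap(traj_a: SSWMTrajectory, traj_b: SSWMTrajectory) -> float:
    """|mutations(A) ∩ mutations(B)| / |mutations(A)|, identity = (pos, to)."""
    a = traj_a.mutations()
    if not a:
        raise ValueError("trajectory A has no mutations")
    return len(a & traj_b.mutations()) / len(a)


def write_trajectory(traj: SSWMTrajectory, path) -> None:
    df = traj.generations.copy()
    df.insert(0, "example_id", traj.example_id)
    df.to_csv(path, sep="\t", index=False)
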