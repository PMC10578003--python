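"""In-silico mutagenesis: saturation scans, importance scores, window
knock-in/knock-out, deep random mutagenesis, and motif insertion.

The central quantity is the per-base importance score derived from a
saturation scan.  With model output p_b for the example carrying base b at
a position (p_ref for the reference base), the score of that position is

    logit(p_ref) - [logit(p_ref) + logit(p_1) + logit(p_2) + logit(p_3)] / 4

— the log-odds of accessibility with the reference base relative to an
average base.  Positive scores mean the reference base opens chromatin
relative to a random base.  By construction the four scores obtained by
treating each base as the reference sum to zero at every position.

Probabilities are clipped to [1e-7, 1 - 1e-7] before the logit so saturated
sigmoids stay finite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import stats

CLIP = 1e-7


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=np.float64), CLIP, 1 - CLIP)
    return np.log(p / (1 - p))


@dataclasses.dataclass
class MutationEffectTable:
    """Saturation-scan outputs: per tissue an (L, 4) matrix of model outputs.

    Column b at row i is the model output with position i substituted to
    base b; the reference base's column holds the unmutated output.
    """

    example_id: str
    ref_onehot: np.ndarray            # (4, L) uint8
    outputs: dict[str, np.ndarray]    # tissue -> (L, 4) float
    ref_output: dict[str, float]

    @property
    def length(self) -> int:
        return self.ref_onehot.shape[1]


@dataclasses.dataclass
class ImportanceTrack:
    example_id: str
    scores: dict[str, np.ndarray]     # tissue -> (L,) float


@dataclasses.dataclass
class WindowHit:
    example_id: str
    tissue: str
    start: int
    length: int
    mean_importance: float
    direction: str                    # "lower" (peak knock-out) or "raise"


@dataclasses.dataclass
class RobustnessResult:
    example_id: str
    retained: dict[str, dict[int, float]]  # tissue -> {n_mut: retained fraction}


# ---------------------------------------------------------------------------
# saturation scan


def _mutant_batch(ref: np.ndarray) -> np.ndarray:
    """All 3L single-base mutants of a (4, L) one-hot, position-major,
    alternatives in base order A<C<G<T (reference base skipped)."""
    L = ref.shape[1]
    ref_base = ref.argmax(axis=0)
    alts = np.array([[b for b in range(4) if b != r] for r in ref_base])  # (L,3)
    muts = np.repeat(ref[None], 3 * L, axis=0)
    pos = np.repeat(np.arange(L), 3)
    new_base = alts.ravel()
    muts[np.arange(3 * L), :, pos] = 0
    muts[np.arange(3 * L), new_base, pos] = 1
    return muts


def saturation_ism(model, example: np.ndarray, example_id: str = "",
                   batch_size: int = 1024, engine: str = "auto") -> MutationEffectTable:
    """Evaluate every single-base substitution (3L mutants + 1 reference).

    ``engine="auto"`` uses the incremental receptive-field scan when the
    model supports it; ``engine="naive"`` always re-runs the full forward
    pass per mutant batch.
    """
    ref = np.asarray(example, dtype=np.uint8)
    if ref.ndim != 2 or ref.shape[0] != 4:
        raise ValueError("example must be a (4, L) one-hot matrix")
    L = ref.shape[1]
    tissues = list(model.config.tissues)
    from .nn import fastscan
    if (engine == "auto" and isinstance(model, fastscan.AccessibilityNet)
            and fastscan.supports_fast_scan(model)):
        p_ref, p_mut = fastscan.predict_all_single_mutants(model, ref, chunk=batch_size)
    else:
        p_ref = model.predict(ref)
        muts = _mutant_batch(ref)
        p_mut = model.predict(muts, batch_size=batch_size)  # (3L, T)
    ref_base = ref.argmax(axis=0)
    alts = np.array([[b for b in range(4) if b != r] for r in ref_base])
    outputs = {}
    for j, t in enumerate(tissues):
        tab = np.empty((L, 4), dtype=np.float64)
        tab[np.arange(L), ref_base] = p_ref[j]
        tab[np.repeat(np.arange(L), 3), alts.ravel()] = p_mut[:, j]
        outputs[t] = tab
    return MutationEffectTable(example_id=example_id, ref_onehot=ref,
                               outputs=outputs,
                               ref_output={t: float(p_ref[j]) for j, t in enumerate(tissues)})


def importance_scores(table: MutationEffectTable) -> ImportanceTrack:
    """logit(p_ref) − mean over the four bases of logit(p_b), per position."""
    ref_base = table.ref_onehot.argmax(axis=0)
    L = table.length
    scores = {}
    for tissue, tab in table.outputs.items():
        lg = logit(tab)
        scores[tissue] = lg[np.arange(L), ref_base] - lg.mean(axis=1)
    return ImportanceTrack(example_id=table.example_id, scores=scores)


def per_base_scores(table: MutationEffectTable, tissue: str) -> np.ndarray:
    """(L, 4) scores treating *each* base as the reference (zero-sum rows).

    This is the "hypothetical contribution" layout used for motif-discovery
    export: row i column b is the importance position i would have if base
    b were the reference.
    """
    lg = logit(table.outputs[tissue])
    return lg - lg.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# population summaries


def mutational_effect_distribution(tables: list[MutationEffectTable],
                                   scale: str = "probability"):
    """Pooled |effect| sample per substitution + log-normal fit summary.

    Effect = |Δ model output| ("probability", the default) or |Δ logit|.
    Returns (effects array, summary dict with mu/sigma of log-effects,
    excess kurtosis of log-effects, and a degeneracy flag).
    """
    if not tables:
        raise ValueError("need at least one effect table")
    pooled = []
    for tb in tables:
        ref_base = tb.ref_onehot.argmax(axis=0)
        L = tb.length
        for tissue, tab in tb.outputs.items():
            vals = logit(tab) if scale == "logit" else tab
            ref_col = vals[np.arange(L), ref_base]
            eff = np.abs(vals - ref_col[:, None])
            mask = np.ones_like(eff, dtype=bool)
            mask[np.arange(L), ref_base] = False
            pooled.append(eff[mask])
    effects = np.concatenate(pooled)
    nonzero = effects[effects > 0]
    if len(nonzero) < 10 or np.ptp(np.log(nonzero)) < 1e-12:
        return effects, {"degenerate": True, "mu": np.nan, "sigma": np.nan,
                         "excess_kurtosis": np.nan}
    logs = np.log(nonzero)
    return effects, {
        "degenerate": False,
        "mu": float(logs.mean()),
        "sigma": float(logs.std(ddof=1)),
        "excess_kurtosis": float(stats.kurtosis(logs, fisher=True)),
        "frac_zero": float(1 - len(nonzero) / len(effects)),
    }


def positional_importance_profile(tracks: list[ImportanceTrack], tissue: str,
                                  bin_width: int = 1) -> np.ndarray:
    """Median |importance| per position (optionally binned) across examples."""
    mats = np.stack([np.abs(tr.scores[tissue]) for tr in tracks])
    prof = np.median(mats, axis=0)
    if bin_width > 1:
        L = len(prof) // bin_width * bin_width
        prof = prof[:L].reshape(-1, bin_width).mean(axis=1)
    return prof


# ---------------------------------------------------------------------------
# window knock-in / knock-out


def best_window(track: ImportanceTrack, tissue: str, predicted_peak: bool,
                window_len: int) -> WindowHit:
    """The window whose ablation would most change the predicted state.

    Predicted peaks: maximize the moving-average importance (these bases
    hold the peak open; knocking them out most lowers the output).
    Predicted non-peaks: minimize it (knock-out most raises the output).
    Ties break to the lowest start.
    """
    s = track.scores[tissue]
    if window_len > len(s):
        raise ValueError("window longer than track")
    mov = np.convolve(s, np.ones(window_len) / window_len, mode="valid")
    start = int(np.argmax(mov) if predicted_peak else np.argmin(mov))
    return WindowHit(example_id=track.example_id, tissue=tissue, start=start,
                     length=window_len, mean_importance=float(mov[start]),
                     direction="lower" if predicted_peak else "raise")


def _replace_center(background: np.ndarray, insert: np.ndarray) -> np.ndarray:
    """Overwrite the central len(insert) columns of a (4, L) one-hot."""
    L, w = background.shape[1], insert.shape[1]
    if w > L:
        raise ValueError("insert longer than background")
    lo = (L - w) // 2
    out = background.copy()
    out[:, lo : lo + w] = insert
    return out


def select_knockin_backgrounds(model, negatives: np.ndarray, n: int = 10,
                               seed: int = 0) -> np.ndarray:
    """The n non-peak examples with the lowest mean model output (seeded
    random tie-break), fixed once and reused for every insertion."""
    probs = model.predict(negatives).mean(axis=1)
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(probs)) * 1e-12
    order = np.argsort(probs + jitter, kind="stable")
    return np.asarray(negatives)[order[:n]]


def knock_in(model, subsequences: list[np.ndarray], backgrounds: np.ndarray,
             labels: np.ndarray):
    """Insert each subsequence into the centre of each fixed background.

    Score of a subsequence = mean model output over the backgrounds.
    Returns (scores (n_subseq, n_tissues), labels) ready for metric
    computation against the original example labels.
    """
    batch = []
    for sub in subsequences:
        for bg in backgrounds:
            batch.append(_replace_center(np.asarray(bg), np.asarray(sub)))
    probs = model.predict(np.stack(batch))
    probs = probs.reshape(len(subsequences), len(backgrounds), -1)
    return probs.mean(axis=1), np.asarray(labels)


def knock_out(model, example: np.ndarray, hit: WindowHit, seed: int = 0):
    """Replace the hit window with iid uniform random bases.

    Returns (mutated example, predictions for it).
    """
    ref = np.asarray(example)
    if not 0 <= hit.start <= ref.shape[1] - hit.length:
        raise ValueError("window out of bounds")
    rng = np.random.default_rng(seed)
    w = hit.length
    rand = np.zeros((4, w), dtype=ref.dtype)
    rand[rng.integers(0, 4, size=w), np.arange(w)] = 1
    mutated = ref.copy()
    mutated[:, hit.start : hit.start + w] = rand
    return mutated, model.predict(mutated)


def knock_out_set(model, examples: np.ndarray, hits: list[WindowHit],
                  seed: int = 0) -> np.ndarray:
    """Vectorized knock-out over a set; returns post-ablation outputs."""
    rng = np.random.default_rng(seed)
    batch = []
    for ex, hit in zip(examples, hits):
        w = hit.length
        rand = np.zeros((4, w), dtype=np.asarray(ex).dtype)
        rand[rng.integers(0, 4, size=w), np.arange(w)] = 1
        m = np.asarray(ex).copy()
        m[:, hit.start : hit.start + w] = rand
        batch.append(m)
    return model.predict(np.stack(batch))


# ---------------------------------------------------------------------------
# deep random mutagenesis


def deep_random_mutagenesis(model, example: np.ndarray, thresholds: dict[str, float],
                            levels=(50, 100, 200, 500), n_experiments: int = 1000,
                            seed: int = 0, example_id: str = "",
                            batch_size: int = 1024) -> RobustnessResult:
    """Fraction of mutational experiments that retain the predicted state.

    Each experiment substitutes ``n_mut`` distinct positions (without
    back-mutation), each to one of the three alternative bases uniformly;
    a state change is the output crossing the tissue threshold.
    """
    ref = np.asarray(example, dtype=np.uint8)
    L = ref.shape[1]
    tissues = list(model.config.tissues)
    p0 = model.predict(ref)
    orig_state = {t: p0[j] > thresholds[t] for j, t in enumerate(tissues)}
    rng = np.random.default_rng(seed)
    retained: dict[str, dict[int, float]] = {t: {} for t in tissues}
    for n_mut in levels:
        if n_mut > L:
            raise ValueError(f"n_mut {n_mut} exceeds example length {L}")
        if n_mut == 0:
            for t in tissues:
                retained[t][0] = 1.0
            continue
        ref_codes = ref.argmax(axis=0)
        changed = np.zeros(len(tissues))
        done = 0
        while done < n_experiments:
            nb = min(batch_size, n_experiments - done)
            # distinct positions per experiment via random-key partial sort
            pos = np.argpartition(rng.random((nb, L)), n_mut - 1, axis=1)[:, :n_mut]
            shift = rng.integers(1, 4, size=(nb, n_mut))
            new = (ref_codes[pos] + shift) % 4
            muts = np.repeat(ref[None], nb, axis=0)
            rows = np.arange(nb)[:, None]
            muts[rows, :, pos] = 0
            muts[rows, new, pos] = 1
            p = model.predict(muts)
            for j, t in enumerate(tissues):
                changed[j] += ((p[:, j] > thresholds[t]) != orig_state[t]).sum()
            done += nb
        for j, t in enumerate(tissues):
            retained[t][int(n_mut)] = 1.0 - changed[j] / n_experiments
    return RobustnessResult(example_id=example_id, retained=retained)


def random_sequence_baseline(model, thresholds: dict[str, float], n: int = 1000,
                             length: int | None = None, seed: int = 0) -> dict[str, float]:
    """Fraction of iid uniform-base sequences classified as peaks."""
    L = length or model.config.input_length
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, L))
    X = np.zeros((n, 4, L), dtype=np.uint8)
    X[np.arange(n)[:, None], codes, np.arange(L)[None, :]] = 1
    p = model.predict(X)
    return {t: float((p[:, j] > thresholds[t]).mean())
            for j, t in enumerate(model.config.tissues)}


# ---------------------------------------------------------------------------
# motif insertion


def motif_insertion_experiment(model, consensus_seqs: dict[str, np.ndarray],
                               examples: np.ndarray, thresholds: dict[str, float]):
    """Insert each consensus centrally into every example; report the
    fraction whose predicted state changes, per motif per tissue."""
    tissues = list(model.config.tissues)
    p0 = model.predict(np.asarray(examples))
    state0 = {t: p0[:, j] > thresholds[t] for j, t in enumerate(tissues)}
    out = {}
    for name, cons in consensus_seqs.items():
        batch = np.stack([_replace_center(np.asarray(ex), np.asarray(cons))
                          for ex in examples])
        p = model.predict(batch)
        out[name] = {t: float(((p[:, j] > thresholds[t]) != state0[t]).mean())
                     for j, t in enumerate(tissues)}
    return out


# ---------------------------------------------------------------------------
# attribution export


def export_attributions(tables: list[MutationEffectTable], out_dir: str | Path) -> Path:
    """Write hypothetical/actual contribution arrays + a manifest.

    Layout: one ``<example_id>.npz`` per example with, per tissue, arrays
    ``hyp_<tissue>`` (L, 4; per-base scores with each base as reference)
    and ``act_<tissue>`` (hyp × one-hot).  ``manifest.json`` lists one
    record per example with file name, length and tissues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for tb in tables:
        arrays = {}
        for tissue in tb.outputs:
            hyp = per_base_scores(tb, tissue)
            arrays[f"hyp_{tissue}"] = hyp.astype(np.float32)
            arrays[f"act_{tissue}"] = (hyp * tb.ref_onehot.T).astype(np.float32)
        fname = f"{tb.example_id or 'example'}.npz"
        np.savez(out_dir / fname, **arrays)
        records.append({"example_id": tb.example_id, "file": fname,
                        "length": tb.length, "tissues": list(tb.outputs)})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"n_examples": len(records),
                                    "records": records}, indent=1))
    return manifest


def load_attribution(out_dir: str | Path, example_id: str) -> dict[str, np.ndarray]:
    with np.load(Path(out_dir) / f"{example_id}.npz") as data:
        return {k: data[k].copy() for k in data.files}
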