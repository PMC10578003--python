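"""Evaluation toolkit: threshold-free metrics, baselines, decision
thresholds, cross-species performance ratios, and the importance ×
conservation correlation.

AUROC is the rank (Mann–Whitney) statistic with ties averaged; AUPR is
step-wise precision–recall integration (average precision).  The decision
threshold for binarizing model outputs maximizes sensitivity × specificity
on validation scores, searching the midpoints of sorted unique scores.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclasses.dataclass
class MetricReport:
    tissue: str
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int


@dataclasses.dataclass
class DecisionThreshold:
    tissue: str
    value: float
    criterion: str = "max sensitivity*specificity on validation"


def compute_metrics(scores, labels, tissue: str = "") -> MetricReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics need at least one positive and one negative")
    return MetricReport(tissue=tissue,
                        auroc=float(roc_auc_score(labels, scores)),
                        aupr=float(average_precision_score(labels, scores)),
                        n_pos=n_pos, n_neg=n_neg)


def gc_content(one_hot_seqs: np.ndarray) -> np.ndarray:
    """GC fraction per example from one-hot (N columns excluded entirely)."""
    x = np.asarray(one_hot_seqs)
    gc = x[:, 1, :].sum(axis=1) + x[:, 2, :].sum(axis=1)
    known = x.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(known > 0, gc / known, 0.0)


def gc_baseline(one_hot_seqs: np.ndarray, labels, tissue: str = "") -> MetricReport:
    """Classification metrics when the score is simply each example's GC."""
    return compute_metrics(gc_content(one_hot_seqs), labels, tissue=tissue)


def choose_threshold(scores_val, labels_val, tissue: str = "") -> DecisionThreshold:
    """Argmax of sensitivity*specificity over candidate cutpoints.

    Candidates are midpoints of consecutive sorted unique scores
    (predicted positive ⇔ score > threshold); ties take the lowest
    threshold.  Degenerate all-equal scores return that value and warn.
    """
    s = np.asarray(scores_val, dtype=float)
    y = np.asarray(labels_val).astype(int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("threshold selection needs both classes")
    uniq = np.unique(s)
    if len(uniq) == 1:
        warnings.warn("all validation scores equal; threshold is degenerate")
        return DecisionThreshold(tissue=tissue, value=float(uniq[0]))
    candidates = (uniq[:-1] + uniq[1:]) / 2
    pred = s[None, :] > candidates[:, None]          # (n_cand, n)
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    product = (tp / (y == 1).sum()) * (tn / (y == 0).sum())
    best = int(np.argmax(product))  # argmax returns the first (lowest) maximizer
    return DecisionThreshold(tissue=tissue, value=float(candidates[best]))


def cross_species_ratio(foreign_report: MetricReport,
                        native_report: MetricReport) -> dict[str, float]:
    """metric(model A on species B) / metric(model B on species B)."""
    out = {}
    for metric in ("auroc", "aupr"):
        denom = getattr(native_report, metric)
        if denom == 0:
            raise ZeroDivisionError(f"native {metric} is zero")
        out[f"{metric}_ratio"] = getattr(foreign_report, metric) / denom
    return out


def importance_conservation_correlation(
    importance_head: np.ndarray,
    importance_testis: np.ndarray,
    track_values: np.ndarray,
    center: int = 200,
) -> tuple[float, float]:
    """Spearman correlation of summed per-base importance vs conservation.

    Inputs are (n_examples, L) arrays aligned base-for-base; only the
    central ``center`` bp of each example enter, pooled across examples.
    """
    ih, it, tv = (np.asarray(a, dtype=float) for a in
                  (importance_head, importance_testis, track_values))
    if ih.shape != it.shape or ih.shape != tv.shape:
        raise ValueError("importance and track arrays must share shape")
    L = ih.shape[1]
    lo = (L - center) // 2
    sl = slice(lo, lo + center)
    summed = (ih + it)[:, sl].ravel()
    cons = tv[:, sl].ravel()
    rho, p = stats.spearmanr(summed, cons)
    return float(rho), float(p)


def compare_output_distributions(group_a, group_b) -> float:
    """One-sided Mann–Whitney U p-value for A stochastically greater than B.

    Exact when n_a + n_b <= 20 and tie-free, else normal approximation with
    tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    small = len(a) + len(b) <= 20
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)
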