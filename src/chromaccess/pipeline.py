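"""The standard in-silico study, end to end.

One call to :func:`run_study` reproduces the core experiment on synthetic
data: generate a six-chromosome genome with planted regulatory motifs,
build 1-kb peak/non-peak examples with the "3L" arm held out, train the
convolution–attention classifier, choose per-tissue decision thresholds on
the validation split, and evaluate on the held-out arm.  The analysis
helpers below run the downstream experiments (mutagenesis, robustness,
greedy evolution, orthology, poised-locus scoring) on the trained study.

Problem sizes default to the package's standard study conditions: a 24-Mb
genome carrying ≈1,900 peaks against ≈20,000 negative tiles, a ≈150k
parameter model, and analysis subsets (examples per mutagenesis analysis,
evolution seeds) sized to run on one CPU in minutes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import evalkit, ism, orthomap, peakdata, sswm, synthio
from .nn import AccessibilityNet, TrainConfig, build_model, train


def derive_seed(seed: int, salt: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def default_spec(seed: int = 0) -> synthio.SyntheticGenomeSpec:
    return synthio.SyntheticGenomeSpec(seed=derive_seed(seed, 1))


def study_train_config(seed: int = 0) -> TrainConfig:
    """The study's compact model: ≈150k parameters, fast on one CPU."""
    return TrainConfig(
        filters_per_layer=(12, 16, 16, 24),
        kernel_size=9,
        attention_heads=2,
        attention_dropout=0.3,
        fc_dropout=0.3,
        fc_hidden=48,
        learning_rate=0.05,
        clip_norm=2.0,
        batch_size=256,
        max_epochs=10,
        patience=11,
        seed=derive_seed(seed, 2),
    )


@dataclasses.dataclass
class Study:
    seed: int
    spec: synthio.SyntheticGenomeSpec
    genome: synthio.Genome
    truth: synthio.Truth
    examples: peakdata.ExampleSet
    model: AccessibilityNet
    history: pd.DataFrame
    thresholds: dict[str, float]
    test_metrics: dict[str, evalkit.MetricReport]
    gc_metrics: dict[str, evalkit.MetricReport]

    @property
    def tissues(self):
        return self.examples.tissues

    def split(self, name: str):
        mask = self.examples.split == name
        return self.examples.subset(mask)


def peaks_by_tissue(truth: synthio.Truth) -> dict[str, list[tuple]]:
    out: dict[str, list[tuple]] = {"head": [], "testis": []}
    for r in truth.peaks.itertuples():
        if r.head:
            out["head"].append((r.chrom, r.start, r.end))
        if r.testis:
            out["testis"].append((r.chrom, r.start, r.end))
    return out


def build_study_examples(genome: synthio.Genome, truth: synthio.Truth,
                         seed: int = 0) -> peakdata.ExampleSet:
    gs = {c: synthio.codes_to_str(s) for c, s in genome.items()}
    return peakdata.build_example_set(gs, peaks_by_tissue(truth),
                                      seed=derive_seed(seed, 3))


def run_study(seed: int = 0, spec: synthio.SyntheticGenomeSpec | None = None,
              config: TrainConfig | None = None, verbose: bool = False) -> Study:
    spec = spec or default_spec(seed)
    config = config or study_train_config(seed)
    genome, truth = synthio.generate_genome(spec)
    examples = build_study_examples(genome, truth, seed=seed)
    splits = examples.split_sets()
    model = build_model(config)
    model, history = train(model, splits["train"], splits["val"], verbose=verbose)

    Xva, yva = splits["val"]
    p_val = model.predict(Xva)
    thresholds = {
        t: evalkit.choose_threshold(p_val[:, j], yva[:, j], tissue=t).value
        for j, t in enumerate(config.tissues)
    }
    Xte, yte = splits["test"]
    p_te = model.predict(Xte)
    test_metrics = {t: evalkit.compute_metrics(p_te[:, j], yte[:, j], tissue=t)
                    for j, t in enumerate(config.tissues)}
    gc_metrics = {t: evalkit.gc_baseline(Xte, yte[:, j], tissue=t)
                  for j, t in enumerate(config.tissues)}
    return Study(seed=seed, spec=spec, genome=genome, truth=truth, examples=examples,
                 model=model, history=history, thresholds=thresholds,
                 test_metrics=test_metrics, gc_metrics=gc_metrics)


def load_study(seed: int, model_path, spec: synthio.SyntheticGenomeSpec | None = None) -> Study:
    """Rebuild a Study around a saved checkpoint.

    The synthetic data are regenerated deterministically from ``seed``;
    thresholds and test metrics are recomputed from the loaded model.
    """
    spec = spec or default_spec(seed)
    genome, truth = synthio.generate_genome(spec)
    examples = build_study_examples(genome, truth, seed=seed)
    model = AccessibilityNet.load(model_path)
    splits = examples.split_sets()
    Xva, yva = splits["val"]
    p_val = model.predict(Xva)
    thresholds = {
        t: evalkit.choose_threshold(p_val[:, j], yva[:, j], tissue=t).value
        for j, t in enumerate(model.config.tissues)
    }
    Xte, yte = splits["test"]
    p_te = model.predict(Xte)
    test_metrics = {t: evalkit.compute_metrics(p_te[:, j], yte[:, j], tissue=t)
                    for j, t in enumerate(model.config.tissues)}
    gc_metrics = {t: evalkit.gc_baseline(Xte, yte[:, j], tissue=t)
                  for j, t in enumerate(model.config.tissues)}
    return Study(seed=seed, spec=spec, genome=genome, truth=truth,
                 examples=examples, model=model, history=pd.DataFrame(),
                 thresholds=thresholds, test_metrics=test_metrics,
                 gc_metrics=gc_metrics)


# ---------------------------------------------------------------------------
# analysis helpers on a trained study


def ism_subset(study: Study, n_pos: int = 80, n_neg: int = 80, seed: int = 0):
    """A balanced, seeded subset of test examples for mutagenesis analyses.

    Returns (X, y, origins_index) with positives first.
    """
    test = study.split("test")
    rng = np.random.default_rng(derive_seed(seed, 4))
    is_pos = test.y.max(axis=1) == 1
    pos_idx = np.flatnonzero(is_pos)
    neg_idx = np.flatnonzero(~is_pos)
    pos_idx = rng.choice(pos_idx, size=min(n_pos, len(pos_idx)), replace=False)
    neg_idx = rng.choice(neg_idx, size=min(n_neg, len(neg_idx)), replace=False)
    idx = np.concatenate([pos_idx, neg_idx])
    return test.X[idx], test.y[idx], test.origins.iloc[idx].reset_index(drop=True)


def compute_ism_tables(study: Study, X: np.ndarray, ids: list[str] | None = None):
    """Saturation tables + importance tracks for a set of examples."""
    tables, tracks = [], []
    for i, x in enumerate(X):
        tb = ism.saturation_ism(study.model, x,
                                example_id=(ids[i] if ids else f"ex{i}"))
        tables.append(tb)
        tracks.append(ism.importance_scores(tb))
    return tables, tracks


@dataclasses.dataclass
class KnockResult:
    window_len: int
    tissue: str
    knockin_auroc: float
    knockout_auroc: float
    original_auroc: float


def knock_analysis(study: Study, X, y, tracks, window_lens=(5, 10),
                   n_backgrounds: int = 10, seed: int = 0) -> list[KnockResult]:
    """Window knock-in / knock-out over a labelled example subset.

    Backgrounds are the ``n_backgrounds`` test non-peak examples with the
    lowest mean model output, fixed once.  Windows are chosen from each
    example's importance track using the model-predicted state (not the
    label), per tissue.
    """
    test = study.split("test")
    neg = test.X[test.y.max(axis=1) == 0]
    backgrounds = ism.select_knockin_backgrounds(study.model, neg, n=n_backgrounds,
                                                 seed=derive_seed(seed, 5))
    p0 = study.model.predict(X)
    results = []
    for j, tissue in enumerate(study.tissues):
        predicted_peak = p0[:, j] > study.thresholds[tissue]
        orig = evalkit.compute_metrics(p0[:, j], y[:, j], tissue=tissue).auroc
        for w in window_lens:
            hits = [ism.best_window(tr, tissue, bool(predicted_peak[i]), w)
                    for i, tr in enumerate(tracks)]
            subs = [X[i][:, h.start : h.start + w] for i, h in enumerate(hits)]
            scores, _ = ism.knock_in(study.model, subs, backgrounds, y)
            ki = evalkit.compute_metrics(scores[:, j], y[:, j], tissue=tissue).auroc
            p_ko = ism.knock_out_set(study.model, X, hits, seed=derive_seed(seed, 6))
            ko = evalkit.compute_metrics(p_ko[:, j], y[:, j], tissue=tissue).auroc
            results.append(KnockResult(w, tissue, ki, ko, orig))
    return results


def robustness_analysis(study: Study, tissue: str = "head", n_examples: int = 16,
                        levels=(50, 100, 200, 500), n_experiments: int = 1000,
                        seed: int = 0):
    """Deep random mutagenesis of true-positive peaks of one tissue.

    Returns (mean retained fraction per level, random-sequence baseline
    fraction, per-example results).
    """
    test = study.split("test")
    j = list(study.tissues).index(tissue)
    p = study.model.predict(test.X[test.y[:, j] == 1])
    X = test.X[test.y[:, j] == 1]
    tp = np.flatnonzero(p[:, j] > study.thresholds[tissue])
    rng = np.random.default_rng(derive_seed(seed, 7))
    chosen = rng.choice(tp, size=min(n_examples, len(tp)), replace=False)
    results = [
        ism.deep_random_mutagenesis(study.model, X[i], study.thresholds,
                                    levels=levels, n_experiments=n_experiments,
                                    seed=derive_seed(seed, 100 + k))
        for k, i in enumerate(chosen)
    ]
    mean_retained = {lv: float(np.mean([r.retained[tissue][lv] for r in results]))
                     for lv in levels}
    baseline = ism.random_sequence_baseline(study.model, study.thresholds,
                                            n=1000, seed=derive_seed(seed, 8))
    return mean_retained, baseline[tissue], results


@dataclasses.dataclass
class SSWMSummary:
    n_seeds: int
    frac_crossed_single: float        # crossed head threshold within the cap
    median_gens_single: float         # censored at cap + 1 when not crossed
    median_gens_opposing: float
    gens_shift_pvalue: float          # one-sided MWU: opposing > single
    overlaps: np.ndarray
    gens_single: np.ndarray
    gens_opposing: np.ndarray
    mean_testis_drag: float           # Δp_testis under head-only selection


def sswm_analysis(study: Study, n_seeds: int = 100, generations: int = 10,
                  seed: int = 0) -> SSWMSummary:
    """Greedy evolution of double-negative examples toward head accessibility,
    with and without opposing selection on the testis.

    Both conditions run the full fixed number of generations (as the walks
    in the source experiments do); generations-to-threshold is read off the
    recorded trajectory, censored at ``generations + 1`` when the head
    threshold is never crossed, and path overlap compares the two
    conditions' complete mutation sets.
    """
    test = study.split("test")
    p = study.model.predict(test.X)
    below = np.ones(len(test.X), dtype=bool)
    for j, t in enumerate(study.tissues):
        below &= (test.y[:, j] == 0) & (p[:, j] <= study.thresholds[t])
    idx = np.flatnonzero(below)
    rng = np.random.default_rng(derive_seed(seed, 9))
    chosen = rng.choice(idx, size=min(n_seeds, len(idx)), replace=False)
    thr = study.thresholds["head"]
    single = sswm.SelectionObjective({"head": +1})
    opposing = sswm.SelectionObjective({"head": +1, "testis": -1})

    def first_crossing(g):
        hit = g[g.p_head > thr]
        return int(hit.generation.iloc[0]) if len(hit) else generations + 1

    gens_s, gens_o, overlaps, drag = [], [], [], []
    for i in chosen:
        x = test.X[i]
        tr_s = sswm.evolve(study.model, x, single, generations=generations)
        tr_o = sswm.evolve(study.model, x, opposing, generations=generations)
        gens_s.append(first_crossing(tr_s.generations))
        gens_o.append(first_crossing(tr_o.generations))
        if tr_s.mutations():
            overlaps.append(sswm.path_overlap(tr_s, tr_o))
        g = tr_s.generations
        drag.append(float(g.p_testis.iloc[-1] - g.p_testis.iloc[0]))
    gens_s = np.array(gens_s)
    gens_o = np.array(gens_o)
    return SSWMSummary(
        n_seeds=len(chosen),
        frac_crossed_single=float((gens_s <= generations).mean()),
        median_gens_single=float(np.median(gens_s)),
        median_gens_opposing=float(np.median(gens_o)),
        gens_shift_pvalue=evalkit.compare_output_distributions(gens_o, gens_s),
        overlaps=np.array(overlaps),
        gens_single=gens_s,
        gens_opposing=gens_o,
        mean_testis_drag=float(np.mean(drag)),
    )


def orthology_analysis(conserve_fraction: float = 0.75, seed: int = 0,
                       spec: synthio.SyntheticGenomeSpec | None = None):
    """Three-species scenario -> orthology calls -> accuracy vs truth.

    Returns (summary DataFrame, dict with conserved fraction and
    species-specific precision/recall pooled over species).
    """
    spec = spec or synthio.SyntheticGenomeSpec(
        n_chromosomes=6, chrom_length=3_000_000, seed=derive_seed(seed, 10))
    scen = synthio.three_species_scenario(spec, conserve_fraction=conserve_fraction,
                                          seed=derive_seed(seed, 11))
    # merge + reciprocal-filter each pair's fragmented map
    ortholog_locations = {}
    for (src, dst), m in scen.maps.items():
        fwd = orthomap.merge_mapped(m)
        back = orthomap.merge_mapped(scen.maps[(dst, src)]
                                     if (dst, src) in scen.maps else m)
        # in this scenario maps are identity, so the back map of a peak is
        # itself; reciprocal filtering uses the source peak set
        kept = orthomap.reciprocal_filter(fwd, fwd, scen.peak_sets[src])
        ortholog_locations[(src, dst)] = kept
    calls = orthomap.classify_orthology(scen.peak_sets, ortholog_locations)
    summary = orthomap.conservation_summary(calls)
    truth = scen.status_truth.set_index(["peak_id", "species"])["status"]
    tp = fp = fn = 0
    n_cons = n_classified = 0
    for c in calls:
        if c.status == "ambiguous_excluded":
            continue
        n_classified += 1
        true = truth.get((c.peak_id, c.species), None)
        if c.status == "conserved":
            n_cons += 1
        if c.status == "species_specific":
            if true == "species_specific":
                tp += 1
            else:
                fp += 1
        elif true == "species_specific":
            fn += 1
    stats = {
        "conserved_fraction": n_cons / n_classified if n_classified else np.nan,
        "specific_precision": tp / (tp + fp) if tp + fp else np.nan,
        "specific_recall": tp / (tp + fn) if tp + fn else np.nan,
    }
    return summary, stats, calls


def poised_analysis(study: Study, rate: float = 0.1, conserve_fraction: float = 0.75,
                    seed: int = 0):
    """Score conserved peaks, lineage-specific peaks, their inaccessible
    orthologs, and plain non-peaks with the trained model (head tissue).

    The sister genome loses motifs at non-conserved peaks down to one
    instance; the orthologous sequence is therefore a "poised" non-peak.
    Only held-out-chromosome loci are scored.  Returns (medians dict,
    one-sided Mann–Whitney p-values dict for each adjacent gap).
    """
    genome2, truth2, _ = synthio.diverge_genome(
        study.genome, study.truth, study.spec, rate=rate,
        conserve_fraction=conserve_fraction, seed=derive_seed(seed, 12))
    test_chrom = "3L"
    conserved_ids = set(truth2.peaks.loc[truth2.peaks.status == "conserved", "peak_id"])
    peaks = study.truth.peaks
    on_test = peaks[peaks.chrom == test_chrom]
    flank = 500

    def window(genome, chrom, mid):
        seq = synthio.codes_to_str(genome[chrom][mid - flank : mid + flank])
        return peakdata.one_hot(seq)

    Xc, Xs, Xo = [], [], []
    for r in on_test.itertuples():
        mid = (r.start + r.end) // 2
        if mid < flank or mid + flank > len(study.genome[r.chrom]):
            continue
        if r.peak_id in conserved_ids:
            Xc.append(window(study.genome, r.chrom, mid))
        else:
            Xs.append(window(study.genome, r.chrom, mid))      # specific peak
            Xo.append(window(genome2, r.chrom, mid))           # poised ortholog
    test = study.split("test")
    Xn = test.X[test.y.max(axis=1) == 0]
    j = list(study.tissues).index("head")
    scores = {
        "non_peaks": study.model.predict(Xn)[:, j],
        "poised_orthologs": study.model.predict(np.stack(Xo))[:, j],
        "specific_peaks": study.model.predict(np.stack(Xs))[:, j],
        "conserved_peaks": study.model.predict(np.stack(Xc))[:, j],
    }
    order = list(scores)
    medians = {k: float(np.median(v)) for k, v in scores.items()}
    pvals = {}
    for lo, hi in zip(order[:-1], order[1:]):
        pvals[f"{hi}>{lo}"] = evalkit.compare_output_distributions(
            scores[hi], scores[lo])
    return medians, pvals, scores


def conservation_correlation_analysis(study: Study, n_random_neg: int = 60,
                                      noise_sd: float = 0.5, seed: int = 0,
                                      test_chrom: str = "3L"):
    """Importance × conservation correlation over inaccessible regions.

    Scores held-out non-peak windows — those centred on silenced decoy loci
    (which carry planted motif content and depressed conservation) plus a
    seeded sample of plain negative tiles — by saturation mutagenesis, sums
    head+testis importance, and Spearman-correlates the central 200 bp
    against the synthetic conservation track.  The planted structure makes
    the true correlation negative in inaccessible regions.
    """
    track = synthio.generate_conservation_track(
        study.genome, study.truth, noise_sd=noise_sd, seed=derive_seed(seed, 13),
        motif_widths={m.id: m.width for m in study.spec.motifs})
    flank = 500
    X, spans = [], []
    sil = study.truth.silenced
    for r in sil[sil.chrom == test_chrom].itertuples():
        mid = (r.start + r.end) // 2
        seq = synthio.codes_to_str(study.genome[r.chrom][mid - flank : mid + flank])
        X.append(peakdata.one_hot(seq))
        spans.append((r.chrom, mid - flank, mid + flank))
    test = study.split("test")
    neg_mask = test.y.max(axis=1) == 0
    rng = np.random.default_rng(derive_seed(seed, 14))
    for i in rng.choice(np.flatnonzero(neg_mask),
                        size=min(n_random_neg, int(neg_mask.sum())), replace=False):
        X.append(test.X[i])
        o = test.origins.iloc[i]
        spans.append((o.chrom, int(o.start), int(o.end)))
    _, tracks = compute_ism_tables(study, np.stack(X))
    ih = np.stack([tr.scores["head"] for tr in tracks])
    it = np.stack([tr.scores["testis"] for tr in tracks])
    tv = np.stack([track[c][s:e] for c, s, e in spans])
    rho, p = evalkit.importance_conservation_correlation(ih, it, tv)
    return rho, p, 200 * len(X)
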