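"""Synthetic genomes with planted regulatory grammar.

This module fabricates everything the analysis needs so that the whole
pipeline runs with no external data: genomes whose accessible regions
("peaks") are driven by planted position-probability-matrix motifs, sister
species derived by neutral substitution with controlled motif conservation,
per-base conservation tracks with a known-sign relationship to the planted
signal, and 1:1 liftover interval maps (optionally fragmented to mimic
alignment-tool output).

The generative model, in brief:

* Background sequence is iid with P(A)=P(T)=(1-gc)/2 and P(C)=P(G)=gc/2.
  Because motifs are planted by *replacing* background bases with draws
  from near-background-GC PPMs, peak and non-peak GC are matched by
  construction and GC content carries essentially no label information.
* Each peak carries several instances of an activating motif near its
  centre.  Peaks come in three tissue flavours (head-only, testis-only,
  shared) and two strengths: peaks destined to be conserved across species
  carry ``instances_conserved`` activating instances, peaks destined to be
  species-specific carry ``instances_specific`` (fewer).  This builds the
  empirical observation that lineage-specific accessible regions look like
  weaker versions of conserved ones directly into the truth.
* A fraction of non-peak loci are "silenced": they carry activating
  instances plus repressor-motif instances and are labelled inaccessible,
  which forces a sequence model to learn the repressive grammar.
* Divergence rewrites each site with probability ``rate`` (always to a
  different base, uniform over the 3 alternatives; no indels, so
  coordinates are shared and liftover maps are exactly 1:1).  Conserved
  peaks have their motif instances re-planted after divergence; lost peaks
  keep only a subset of instances in the derived genome ("poised" partial
  motif content); gained peaks appear at dedicated loci that are poised in
  the other genome.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_ORDER = "ACGT"

# ---------------------------------------------------------------------------
# sequence helpers (uint8 codes 0..3 internally)


def codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()

def str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASE_ORDER):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        pos = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT character {seq[pos]!r} at position {pos}")
    return codes


# ---------------------------------------------------------------------------
# domain types


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """A position-probability matrix with a signed accessibility effect."""

    id: str
    matrix: np.ndarray          # (width, 4), rows sum to 1
    effect: float               # >0 activating, <0 repressive
    tissues: tuple[str, ...]    # tissues the motif acts in

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("motif matrix must be (width>=4, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6) or (m < 0).any():
            raise ValueError("motif matrix rows must be probability simplices")
        if self.effect == 0:
            raise ValueError("motif effect must be nonzero")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return codes_to_str(self.matrix.argmax(axis=1).astype(np.uint8))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        cum = self.matrix.cumsum(axis=1)
        u = rng.random(self.width)[:, None]
        return (u > cum[:, :3]).sum(axis=1).astype(np.uint8)


def _sharp_ppm(consensus: str, p: float = 0.85) -> np.ndarray:
    codes = str_to_codes(consensus)
    m = np.full((len(codes), 4), (1 - p) / 3)
    m[np.arange(len(codes)), codes] = p
    return m


def default_motifs() -> list[MotifModel]:
    """The planted regulatory vocabulary used throughout the analysis.

    Consensus strings are arbitrary 8-mers with 50% GC so that planting
    them barely perturbs local GC content at the default background.
    """
    return [
        MotifModel("act_shared", _sharp_ppm("TGACGTCA"), +1.0, ("head", "testis")),
        MotifModel("act_head", _sharp_ppm("AGGCCTAA"), +1.0, ("head",)),
        MotifModel("act_testis", _sharp_ppm("TTCGCGAA"), +1.0, ("testis",)),
        MotifModel("rep_shared", _sharp_ppm("ACTAGTTC"), -1.0, ("head", "testis")),
    ]


@dataclasses.dataclass
class SyntheticGenomeSpec:
    """Study conditions for one synthetic genome.

    Defaults are sized so that the full pipeline (≈2,000 peaks against
    ≈20,000 negative 1-kb tiles over a 24-Mb six-chromosome genome with a
    held-out "3L") trains and evaluates on one CPU.
    """

    n_chromosomes: int = 6
    chrom_length: int = 4_000_000
    gc: float = 0.42
    motifs: list[MotifModel] = dataclasses.field(default_factory=default_motifs)
    peak_rate: float = 8.0          # expected peaks per 100 kb
    peak_width: int = 400
    instances_conserved: int = 3    # activating instances in a conserved-class peak
    instances_specific: int = 2     # ... in a species-specific-class peak
    specific_fraction: float = 0.25 # fraction of peaks destined to be lineage-specific
    silenced_per_chrom: int = 30    # non-peak loci carrying activators + repressors
    tissue_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)  # head / testis / shared
    divergence_levels: tuple[float, ...] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.peak_width < 50:
            raise ValueError("peak_width must be >= 50")
        for d in self.divergence_levels:
            if not 0.0 <= d <= 0.5:
                raise ValueError("divergence levels must be in [0, 0.5]")
        # peaks are laid out on a non-overlapping grid of 2-kb slots with
        # 1-kb spacing; refuse rates the packing cannot accommodate
        if self.peak_rate * (self.peak_width + 2600) > 100_000:
            raise ValueError(
                f"peak_rate {self.peak_rate}/100kb implies peaks denser than "
                "non-overlapping 1-kb example windows allow"
            )

    def chrom_names(self) -> list[str]:
        canonical = ["2L", "2R", "3L", "3R", "X", "4"]
        if self.n_chromosomes <= len(canonical):
            return canonical[: self.n_chromosomes]
        return canonical + [f"chr{i}" for i in range(len(canonical), self.n_chromosomes)]


@dataclasses.dataclass
class Truth:
    """Ground truth emitted alongside a genome."""

    peaks: pd.DataFrame    # chrom,start,end,peak_id,head,testis,cls,n_instances
    motifs: pd.DataFrame   # chrom,start,strand,motif_id,peak_id
    silenced: pd.DataFrame # chrom,start,end,locus_id


Genome = dict[str, np.ndarray]  # chrom -> uint8 codes


# ---------------------------------------------------------------------------
# generation


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


def _plant(seq: np.ndarray, pos: int, motif: MotifModel, strand: str,
           rng: np.random.Generator) -> None:
    inst = motif.sample(rng)
    if strand == "-":
        inst = _revcomp(inst)
    seq[pos : pos + motif.width] = inst


def _activators_for(motifs: list[MotifModel], flavour: str) -> list[MotifModel]:
    if flavour == "shared":
        want = {"head", "testis"}
        return [m for m in motifs if m.effect > 0 and set(m.tissues) >= want]
    return [m for m in motifs if m.effect > 0 and m.tissues == (flavour,)]


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[Genome, Truth]:
    """Generate a genome and its truth tables (deterministic in spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    genome: Genome = {}
    peak_rows, motif_rows, sil_rows = [], [], []
    activators_present = any(m.effect > 0 for m in spec.motifs)
    repressors = [m for m in spec.motifs if m.effect < 0]
    pid = 0
    for chrom in spec.chrom_names():
        seq = _background(rng, spec.chrom_length, spec.gc)
        n_peaks = int(round(spec.peak_rate * spec.chrom_length / 100_000))
        if not activators_present:
            n_peaks = 0  # no signal, no peaks
        # non-overlapping slots: peak windows (1 kb, centred) spaced >= 1 kb apart
        slot = 2000 + spec.peak_width
        margin = 2000
        n_slots = (spec.chrom_length - 2 * margin) // slot
        n_extra = min(spec.silenced_per_chrom if activators_present else 0,
                      max(0, n_slots - n_peaks))
        chosen = rng.choice(n_slots, size=n_peaks + n_extra, replace=False)
        chosen.sort()
        peak_slots, silenced_slots = chosen[:n_peaks], chosen[n_peaks:]
        # interleave classes deterministically via rng draws
        for s in peak_slots:
            start = margin + int(s) * slot + 1000
            end = start + spec.peak_width
            flavour = ("head", "testis", "shared")[
                rng.choice(3, p=np.asarray(spec.tissue_probs) / sum(spec.tissue_probs))
            ]
            cls = "specific" if rng.random() < spec.specific_fraction else "conserved"
            n_inst = (spec.instances_specific if cls == "specific"
                      else spec.instances_conserved)
            acts = _activators_for(spec.motifs, flavour)
            positions = _instance_positions(rng, start, end, n_inst,
                                            max(m.width for m in acts))
            for p in positions:
                motif = acts[rng.integers(len(acts))]
                _plant(seq, p, motif, "+", rng)
                motif_rows.append({"chrom": chrom, "start": p, "strand": "+",
                                   "motif_id": motif.id, "peak_id": f"pk{pid}"})
            peak_rows.append({"chrom": chrom, "start": start, "end": end,
                              "peak_id": f"pk{pid}",
                              "head": int(flavour in ("head", "shared")),
                              "testis": int(flavour in ("testis", "shared")),
                              "cls": cls, "n_instances": n_inst})
            pid += 1
        for s in silenced_slots:
            start = margin + int(s) * slot + 1000
            end = start + spec.peak_width
            acts = _activators_for(spec.motifs, "shared") or \
                [m for m in spec.motifs if m.effect > 0]
            width = max(m.width for m in acts + repressors) if (acts or repressors) else 8
            positions = _instance_positions(rng, start, end, 2 + 2 * bool(repressors), width)
            locus = f"sil{chrom}_{int(s)}"
            for i, p in enumerate(positions):
                pool = acts if i < 2 else repressors
                if not pool:
                    continue
                motif = pool[rng.integers(len(pool))]
                _plant(seq, p, motif, "+", rng)
                motif_rows.append({"chrom": chrom, "start": p, "strand": "+",
                                   "motif_id": motif.id, "peak_id": locus})
            sil_rows.append({"chrom": chrom, "start": start, "end": end,
                             "locus_id": locus})
        genome[chrom] = seq
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "peak_id",
                                             "head", "testis", "cls", "n_instances"])
    motifs = pd.DataFrame(motif_rows, columns=["chrom", "start", "strand",
                                               "motif_id", "peak_id"])
    silenced = pd.DataFrame(sil_rows, columns=["chrom", "start", "end", "locus_id"])
    return genome, Truth(peaks=peaks, motifs=motifs, silenced=silenced)


def _instance_positions(rng: np.random.Generator, start: int, end: int,
                        n: int, width: int) -> list[int]:
    """Non-overlapping motif start positions inside the central half of a peak."""
    centre = (start + end) // 2
    span = max((end - start) // 2, (width + 4) * n)
    lo = centre - span // 2
    offsets = rng.permutation(span // (width + 4))[:n]
    return sorted(lo + int(o) * (width + 4) for o in offsets)


# ---------------------------------------------------------------------------
# divergence


def diverge_genome(
    genome: Genome,
    truth: Truth,
    spec: SyntheticGenomeSpec,
    rate: float,
    conserve_fraction: float,
    seed: int,
    gain_per_chrom: int = 0,
    poised_instances: int = 1,
    fragment_maps: bool = True,
) -> tuple[Genome, Truth, pd.DataFrame]:
    """Derive a sister genome by neutral substitution plus motif turnover.

    ``conserve_fraction`` of peaks keep their planted motifs (re-planted
    after substitution); the remainder lose them down to
    ``poised_instances`` surviving instances (partial motif content — the
    orthologous locus is inaccessible but "poised").  ``gain_per_chrom``
    extra peaks are planted at background loci of the derived genome,
    producing peaks specific to the new species.  Returns the new genome,
    its truth, and a liftover interval map between the two coordinate
    systems (identical coordinates; no indels).
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError("substitution rate must be in [0, 0.5]")
    if not 0.0 <= conserve_fraction <= 1.0:
        raise ValueError("conserve_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genome2: Genome = {}
    for chrom, seq in genome.items():
        new = seq.copy()
        if rate > 0:
            hit = rng.random(len(seq)) < rate
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            new[hit] = (new[hit] + shift) % 4
        genome2[chrom] = new

    peaks = truth.peaks.copy()
    keep_mask = np.zeros(len(peaks), dtype=bool)
    if len(peaks):
        # peaks pre-assigned class "conserved" are preferred keepers so the
        # planted strength classes line up with orthology status
        order = np.argsort((peaks["cls"] == "specific").to_numpy(), kind="stable")
        n_keep = int(round(conserve_fraction * len(peaks)))
        keep_mask[order[:n_keep]] = True

    peak_rows2, motif_rows2 = [], []
    by_peak = dict(tuple(truth.motifs.groupby("peak_id"))) if len(truth.motifs) else {}
    for i, row in peaks.reset_index(drop=True).iterrows():
        insts = by_peak.get(row.peak_id)
        insts = insts.sort_values("start") if insts is not None else pd.DataFrame()
        width_of = {m.id: m.width for m in spec.motifs}
        motif_of = {m.id: m for m in spec.motifs}
        if keep_mask[i]:
            for _, mr in insts.iterrows():
                motif = motif_of[mr.motif_id]
                genome2[row.chrom][mr.start : mr.start + motif.width] = \
                    genome[row.chrom][mr.start : mr.start + motif.width]
                motif_rows2.append({"chrom": row.chrom, "start": mr.start,
                                    "strand": mr.strand, "motif_id": mr.motif_id,
                                    "peak_id": row.peak_id})
            peak_rows2.append({**row.to_dict(), "status": "conserved"})
        else:
            # overwrite all but `poised_instances` instances with background
            survivors = insts.iloc[:poised_instances]
            for _, mr in insts.iterrows():
                w = width_of[mr.motif_id]
                if mr.start in set(survivors["start"]):
                    genome2[row.chrom][mr.start : mr.start + w] = \
                        genome[row.chrom][mr.start : mr.start + w]
                    motif_rows2.append({"chrom": row.chrom, "start": mr.start,
                                        "strand": mr.strand, "motif_id": mr.motif_id,
                                        "peak_id": row.peak_id + "_poised"})
                else:
                    genome2[row.chrom][mr.start : mr.start + w] = \
                        _background(rng, w, spec.gc)
    peaks_out = pd.DataFrame([r for r in peak_rows2],
                             columns=list(peaks.columns) + ["status"])

    # gained peaks: new accessible loci specific to the derived genome
    gain_rows = []
    if gain_per_chrom > 0:
        for chrom in genome2:
            occupied = peaks[peaks.chrom == chrom]
            occ = list(zip(occupied.start, occupied.end))
            length = len(genome2[chrom])
            tries = 0
            planted = 0
            while planted < gain_per_chrom and tries < 1000:
                tries += 1
                start = int(rng.integers(3000, length - 3000 - spec.peak_width))
                end = start + spec.peak_width
                if any(s - 2000 < end and start < e + 2000 for s, e in occ):
                    continue
                occ.append((start, end))
                acts = _activators_for(spec.motifs, "shared") or \
                    [m for m in spec.motifs if m.effect > 0]
                positions = _instance_positions(rng, start, end,
                                                spec.instances_specific,
                                                max(m.width for m in acts))
                gid = f"gain_{chrom}_{planted}"
                for p in positions:
                    motif = acts[rng.integers(len(acts))]
                    _plant(genome2[chrom], p, motif, "+", rng)
                    motif_rows2.append({"chrom": chrom, "start": p, "strand": "+",
                                        "motif_id": motif.id, "peak_id": gid})
                gain_rows.append({"chrom": chrom, "start": start, "end": end,
                                  "peak_id": gid, "head": 1, "testis": 1,
                                  "cls": "specific", "n_instances": spec.instances_specific,
                                  "status": "gained"})
                planted += 1
    if gain_rows:
        peaks_out = pd.concat([peaks_out, pd.DataFrame(gain_rows)], ignore_index=True)

    truth2 = Truth(peaks=peaks_out,
                   motifs=pd.DataFrame(motif_rows2, columns=["chrom", "start", "strand",
                                                             "motif_id", "peak_id"]),
                   silenced=truth.silenced.copy())
    liftover = build_liftover_map(truth.peaks, rng if fragment_maps else None)
    return genome2, truth2, liftover


def build_liftover_map(peaks: pd.DataFrame,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """1:1 interval map for every source peak (coordinates are shared).

    With an rng, each peak's mapping is fragmented into 2–4 sub-intervals
    separated by small (<=30 bp) gaps, mimicking the many short intervals an
    alignment liftover emits; merging at a 100-bp tolerance reconstitutes
    the union exactly.
    """
    rows = []
    for _, row in peaks.iterrows():
        pieces = [(row.start, row.end)]
        if rng is not None and row.end - row.start > 120:
            n_frag = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(
                np.arange(row.start + 20, row.end - 20), size=n_frag - 1, replace=False))
            bounds = [row.start, *cuts.tolist(), row.end]
            pieces = []
            for a, b in zip(bounds[:-1], bounds[1:]):
                gap = int(rng.integers(0, 16))
                if b - a > 2 * gap + 4:
                    pieces.append((a + gap, b - gap))
                else:
                    pieces.append((a, b))
        for a, b in pieces:
            rows.append({"src_chrom": row.chrom, "src_start": a, "src_end": b,
                         "peak_id": row.peak_id, "dst_chrom": row.chrom,
                         "dst_start": a, "dst_end": b})
    return pd.DataFrame(rows, columns=["src_chrom", "src_start", "src_end", "peak_id",
                                       "dst_chrom", "dst_start", "dst_end"])


# ---------------------------------------------------------------------------
# conservation track


def generate_conservation_track(
    genome: Genome,
    truth: Truth,
    noise_sd: float = 0.5,
    seed: int = 0,
    motif_widths: dict[str, int] | None = None,
    elevation: float = 2.0,
) -> dict[str, np.ndarray]:
    """Per-base conservation scores with known structure.

    Planted motif bases inside true peaks get +elevation (conserved to stay
    open); planted motif bases at silenced/poised non-peak loci get
    -elevation (accelerated / selected to stay closed); everything else is
    0, plus iid Gaussian noise of sd ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    peak_ids = set(truth.peaks.peak_id)
    track: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        t = np.zeros(len(seq), dtype=np.float32)
        track[chrom] = t
    for _, mr in truth.motifs.iterrows():
        w = (motif_widths or {}).get(mr.motif_id, 8)
        sign = 1.0 if mr.peak_id in peak_ids else -1.0
        track[mr.chrom][mr.start : mr.start + w] += sign * elevation
    if noise_sd > 0:
        for chrom in track:
            track[chrom] = track[chrom] + \
                rng.normal(0.0, noise_sd, size=len(track[chrom])).astype(np.float32)
    return track


# ---------------------------------------------------------------------------
# file output


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            s = codes_to_str(genome[chrom])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_truth_bed(truth: Truth, path: str | Path) -> None:
    """BED6: name = peak_id|head,testis flags, score = n_instances."""
    with open(path, "w") as fh:
        for r in truth.peaks.itertuples():
            name = f"{r.peak_id}|h{r.head}t{r.testis}|{r.cls}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.n_instances}\t.\n")


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path,
                     tissue: str | None = None) -> None:
    """10-column narrowPeak; summit = interval midpoint offset."""
    with open(path, "w") as fh:
        for r in peaks.itertuples():
            if tissue is not None and not getattr(r, tissue):
                continue
            summit = (r.end - r.start) // 2
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\t0\t.\t"
                     f"0\t-1\t-1\t{summit}\n")


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "summit"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def write_motif_ledger(truth: Truth, path: str | Path) -> None:
    truth.motifs.to_csv(path, sep="\t", index=False)


def write_liftover(liftover: pd.DataFrame, path: str | Path,
                   dst_context: str = "") -> None:
    df = liftover.copy()
    df["dst_context"] = dst_context
    df.to_csv(path, sep="\t", index=False)


def read_liftover(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(track: dict[str, np.ndarray], path: str | Path,
                   decimals: int = 3) -> None:
    with open(path, "w") as fh:
        for chrom, values in track.items():
            v = np.round(values.astype(float), decimals)
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


# ---------------------------------------------------------------------------
# multi-species scenario


@dataclasses.dataclass
class SpeciesScenario:
    """Three sister genomes plus peak sets, maps, and orthology truth."""

    species: list[str]
    genomes: dict[str, Genome]
    truths: dict[str, Truth]
    peak_sets: dict[str, pd.DataFrame]            # per species: chrom,start,end,peak_id
    maps: dict[tuple[str, str], pd.DataFrame]     # (src, dst) -> liftover table
    status_truth: pd.DataFrame                    # peak_id,species,status


def three_species_scenario(
    spec: SyntheticGenomeSpec,
    conserve_fraction: float = 0.75,
    rate: float = 0.1,
    loss_fraction: float = 0.0,
    seed: int = 0,
) -> SpeciesScenario:
    """Build species A, B, C with controlled peak conservation.

    ``conserve_fraction`` is the expected conserved fraction of each
    species' own peak set: with presence-pattern probabilities
    P(all three) = f/(3-2f) and P(specific to species i) = (1-f)/(3-2f)
    per species, each peak set is a fraction f conserved in expectation.
    ``loss_fraction`` converts that share of would-be conserved peaks into
    single-lineage losses (present in exactly two species; still conserved
    for the two carriers).  Peak coordinates are shared across species
    (substitution-only divergence), so liftover maps are identity maps,
    fragmented as real liftover output would be.
    """
    rng = np.random.default_rng(seed)
    base_spec = dataclasses.replace(spec, seed=seed)
    genome, truth = generate_genome(base_spec)
    species = ["A", "B", "C"]
    n = len(truth.peaks)
    f = conserve_fraction
    p_conserved = f / (3 - 2 * f)
    u = rng.random(n)
    pattern = np.empty(n, dtype=object)
    for i in range(n):
        if u[i] < p_conserved:
            if rng.random() < loss_fraction:
                lost = rng.integers(3)
                pattern[i] = tuple(0 if j == lost else 1 for j in range(3))
            else:
                pattern[i] = (1, 1, 1)
        else:
            only = rng.integers(3)
            pattern[i] = tuple(1 if j == only else 0 for j in range(3))

    genomes, truths, peak_sets = {}, {}, {}
    status_rows = []
    for si, sp in enumerate(species):
        g = {c: s.copy() for c, s in genome.items()}
        if rate > 0 and si > 0:  # species A keeps ancestral sequence
            for chrom, seqarr in g.items():
                hit = rng.random(len(seqarr)) < rate
                shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
                seqarr[hit] = (seqarr[hit] + shift) % 4
        present = np.array([p[si] for p in pattern], dtype=bool)
        pk = truth.peaks.loc[present, ["chrom", "start", "end", "peak_id"]].copy()
        genomes[sp] = g
        truths[sp] = truth
        peak_sets[sp] = pk.reset_index(drop=True)
        for i in range(n):
            if present[i]:
                n_present = sum(pattern[i])
                status = "conserved" if n_present >= 2 else "species_specific"
                status_rows.append({"peak_id": truth.peaks.peak_id.iloc[i],
                                    "species": sp, "status": status})
    maps = {}
    for src in species:
        for dst in species:
            if src == dst:
                continue
            maps[(src, dst)] = build_liftover_map(peak_sets[src], rng)
    return SpeciesScenario(species=species, genomes=genomes, truths=truths,
                           peak_sets=peak_sets, maps=maps,
                           status_truth=pd.DataFrame(status_rows))
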