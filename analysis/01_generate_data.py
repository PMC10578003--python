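"""Generate the study's synthetic data: a six-chromosome genome with
planted tissue-specific regulatory motifs, its truth tables, a diverged
sister genome with a 1:1 liftover map, and a conservation track.

Writes FASTA / BED / narrowPeak / TSV / bedGraph files under results/data.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chromaccess import synthio
from chromaccess.pipeline import default_spec, derive_seed

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_spec(SEED)
    genome, truth = synthio.generate_genome(spec)
    n_bp = sum(len(s) for s in genome.values())
    print(f"genome: {len(genome)} chromosomes, {n_bp/1e6:.1f} Mb, GC target {spec.gc}")
    print(f"peaks: {len(truth.peaks)} "
          f"(head-only {((truth.peaks['head'] == 1) & (truth.peaks['testis'] == 0)).sum()}, "
          f"testis-only {((truth.peaks['head'] == 0) & (truth.peaks['testis'] == 1)).sum()}, "
          f"shared {((truth.peaks['head'] == 1) & (truth.peaks['testis'] == 1)).sum()})")
    print(f"planted motif instances: {len(truth.motifs)}; "
          f"silenced decoy loci: {len(truth.silenced)}")

    synthio.write_fasta(genome, OUT / "genome.fa")
    synthio.write_truth_bed(truth, OUT / "peaks.bed")
    for tissue in ("head", "testis"):
        synthio.write_narrowpeak(truth.peaks, OUT / f"{tissue}.narrowPeak",
                                 tissue=tissue)
    synthio.write_motif_ledger(truth, OUT / "motifs.tsv")

    genome2, truth2, liftover = synthio.diverge_genome(
        genome, truth, spec, rate=0.1, conserve_fraction=0.75,
        seed=derive_seed(SEED, 20))
    synthio.write_fasta(genome2, OUT / "genome_sister.fa")
    synthio.write_truth_bed(truth2, OUT / "peaks_sister.bed")
    synthio.write_liftover(liftover, OUT / "liftover.tsv", dst_context="sister")
    kept = (truth2.peaks.status == "conserved").sum()
    print(f"sister genome at 10% divergence: {kept} conserved peaks, "
          f"{len(truth.peaks) - kept} lineage-specific (orthologs left poised)")

    track = synthio.generate_conservation_track(
        genome, truth, noise_sd=0.5, seed=derive_seed(SEED, 13),
        motif_widths={m.id: m.width for m in spec.motifs})
    synthio.write_bedgraph(track, OUT / "conservation.bedGraph")
    print(f"wrote all files to {OUT}")


if __name__ == "__main__":
    main()
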