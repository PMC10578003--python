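# chromaccess

Sequence-based modelling of tissue-specific chromatin accessibility and its
evolution, with a fully synthetic planted-motif benchmark.

## What this is for

ATAC-seq assigns each genomic region an accessibility state per tissue.
This package asks how far that state is determined by *local DNA sequence
alone*, and then uses the fitted sequence model as an instrument for
questions that are intractable at the bench:

- Which bases matter?  (saturation in-silico mutagenesis and per-base
  importance scores)
- Can accessibility be predicted from very short subsequences, and does
  deleting them destroy it?  (window knock-in / knock-out)
- How robust is the accessibility state to large-scale random mutation?
  (50–500 substitutions per kilobase, 1000 experiments per region)
- How malleable is it under strong selection?  (greedy strong-selection
  weak-mutation evolution, with single-tissue, joint, and opposing
  objectives)
- Which peaks are conserved between species and which are
  lineage-specific?  (reference-agnostic multi-context liftover orthology)

It is aimed at regulatory-genomics researchers who want these analyses as
importable, tested building blocks.  Everything runs end to end on
synthetic genomes with planted ground truth — no downloads — so every
analysis can be validated against a known generative process before being
pointed at real data (FASTA + MACS2 narrowPeak + liftover interval maps).

## The model

A two-task classifier maps a 1-kb one-hot sequence to per-tissue
accessibility probabilities (head and testis):

    4 x [conv -> batch norm -> ReLU -> maxpool(2)]   (shared)
      -> + sinusoidal positional encoding
      -> multi-head self-attention                    (shared)
      -> per tissue: linear -> dropout -> ReLU -> linear -> sigmoid

trained with the summed per-tissue binary cross-entropy, SGD with momentum
and gradient clipping, and patience-11 early stopping that restores the
validation-loss minimum.  Positive examples are peak-midpoint ± 500 bp
windows; negatives are 1-kb tiles overlapping no peak; one chromosome arm
(3L) is always held out.  Per-base importance is the log-odds of the
reference base against the average base,
`logit(p_ref) − ¼·Σ_b logit(p_b)`, computed from a saturation scan of all
3·L single-base mutants (an incremental receptive-field scanner makes this
~13× faster than naive re-prediction; see `docs/methods.md`).

The network and its backpropagation are implemented in numpy and verified
against finite differences in the test suite.

## Worked example

Generate a synthetic study genome, train the classifier, and evaluate it:

```bash
python analysis/01_generate_data.py
python analysis/02_train_model.py
```

which prints (seed 1):

```
genome: 6 chromosomes, 24.0 Mb, GC target 0.42
peaks: 1920 (head-only 569, testis-only 585, shared 766)
planted motif instances: 5968; silenced decoy loci: 180
...
head: AUROC 0.960  AUPR 0.770  (GC baseline AUROC 0.531)  threshold 0.1416
testis: AUROC 0.962  AUPR 0.806  (GC baseline AUROC 0.537)  threshold 0.2334
```

The model recovers the planted regulatory grammar almost perfectly while
GC content alone carries no signal (AUROC ≈ 0.5) — the generator
GC-matches peaks and background precisely so that this control is
meaningful.  The thresholds are the per-tissue cutoffs maximising
sensitivity × specificity on validation, used by every downstream analysis
to binarize "predicted peak" vs "predicted non-peak".

The numbered drivers under `analysis/` continue the study from the saved
checkpoint: `03` saturation mutagenesis (effect-size distribution,
positional importance, conservation correlation, attribution export),
`04` knock-in/knock-out, `05` deep random mutagenesis, `06` in-silico
evolution, `07` three-species orthology, `08` poised-locus scoring, `09`
cross-species generalization.  Each prints its findings and writes tables
under `results/`.  For example, `05` reports the robustness profile of
true-positive peaks:

```
 50 substitutions (5% divergence): mean retained-state fraction 0.944
100 substitutions (10% divergence): mean retained-state fraction 0.844
200 substitutions (20% divergence): mean retained-state fraction 0.606
500 substitutions (50% divergence): mean retained-state fraction 0.122
random-sequence baseline (fraction classified as head peak): 0.047
```

— accessibility degrades smoothly with mutational load and stays far above
the random-sequence baseline even at 20 % divergence, while `06` shows the
opposite face: under strong selection a closed region typically crosses
the open-chromatin threshold within 2 mutations (median; 5 under opposing
selection in the other tissue, with 98 % of seeds taking mostly distinct
mutational paths in the two conditions).

Library use mirrors the drivers:

```python
from chromaccess import pipeline
study = pipeline.run_study(seed=1)                  # generate + train + evaluate
ss = pipeline.sswm_analysis(study, n_seeds=100)     # greedy evolution, 2 conditions
```

A thin CLI covers the file-oriented stages (`chromaccess synthgen / build /
train / metrics`); run `chromaccess --help`.

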