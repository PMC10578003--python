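# Methods

`chromaccess` models tissue-specific chromatin accessibility from local DNA
sequence and uses the trained model as an instrument for in-silico genetics:
saturation mutagenesis, window knock-in/knock-out, deep random mutagenesis,
greedy evolution under strong selection, and cross-species peak-orthology
analysis.  Everything runs end to end on synthetic data with planted ground
truth, so each downstream claim can be checked against a known generative
process.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmark does and does not show.

## The classification problem

Accessible chromatin (ATAC-seq peaks, two tissues: head and testis) is
predicted from 1-kb one-hot DNA windows as a two-task binary classification.
Positive examples are windows of midpoint ± 500 bp around tissue-merged
peaks; negatives are non-overlapping 1-kb genome tiles that touch no merged
peak.  Both tissues share the input; labels are tissue-specific (a merged
peak is labelled 1 in every tissue whose peak calls it overlaps).
Coordinates are 0-based half-open throughout; peak midpoints round down;
trailing partial tiles are dropped; examples with more than 10 % ambiguous
bases are dropped, and remaining `N`s encode as all-zero columns.  One
chromosome arm ("3L", one sixth of the genome) is held out for testing; a
seeded uniform 10 % of the remainder is the validation split (
`floor(0.1·n)` examples, unstratified).

## Model

Four shared convolution blocks (same-padded conv → batch norm → ReLU →
max-pool 2), a fixed sinusoidal positional encoding added to the resulting
62-token sequence, one shared multi-head self-attention layer, and one
fully connected head per tissue (linear → dropout → ReLU → linear →
sigmoid) reading the flattened attention output.  The loss is the sum over
tissues of the per-tissue mean binary cross-entropy; optimization is SGD
with momentum; early stopping restores the parameters of the
validation-loss minimum after 11 epochs without strict improvement.

The network and its backpropagation are implemented directly in numpy
(channels-last layout; conv as im2col + GEMM).  Gradients are verified
against central finite differences in float64 in the test suite.  Numerical
choices worth knowing:

- **Floor pooling.** 1000 is not divisible by 2⁴; each pool drops a
  trailing odd element (1000 → 500 → 250 → 125 → 62).  The positional
  encoding length is the post-conv token count.
- **Gradient clipping.** The residual-free attention stack diverges under
  plain SGD at useful learning rates; updates are rescaled when the global
  gradient norm exceeds `clip_norm` (default 5; the study config uses 2).
- **Stability.** Training BCE is computed from logits
  (`max(z,0) − zy + log(1+e^{−|z|})`); inference probabilities are clipped
  to `[1e−7, 1−1e−7]` before any logit transform, capping log-odds at
  ±16.1.
- **Determinism.** Initialisation, shuffling, and dropout derive from the
  config seed; inference uses running batch-norm statistics with dropout
  off, so repeated predictions are identical.

`TrainConfig` defaults describe a full-size model (kernel 7, 4×128
filters, 4 heads, dropout 0.3, lr 0.01, momentum 0.9, batch 256, patience
11).  The *study* configuration used by the pipeline and the analysis
drivers is deliberately compact — filters (12, 16, 16, 24), kernel 9, 2
attention heads, attention and FC dropout 0.3, lr 0.05 with clip 2, 10
epochs, ≈154k parameters — sized so the whole study trains in minutes on
one CPU while still reaching AUROC ≈ 0.97 on the synthetic benchmark.
Attention dropout matters beyond regularisation here: without it the model
leans on the single strongest motif instance per peak, and window-ablation
effects become even more concentrated.

Hyperparameter search (`nn.tune`) minimises validation loss over a
pluggable suggest/observe engine; the bundled engine is seeded random
search, and a TPE-style optimizer can be plugged in without code changes.

## The fast mutant scan

Saturation mutagenesis and greedy evolution score all 3L single-base
mutants of a sequence (3000 for 1 kb).  A naive scan re-runs the full
network per mutant; `nn/fastscan.py` instead caches the reference
activations and, per mutant, recomputes only the conv-stack columns inside
the mutation's receptive field (a changed range of width W feeds a conv
range W + 2·(k//2), which pools to at most (W+2p)//2 + 1 columns; widths
are fixed per level and starts clamped, so the gathers vectorise).  The
patched token matrices then run through attention and the heads in
batches.  The scan is validated against the naive forward pass (agreement
to ~3 × 10⁻⁷; differences are float32 GEMM-shape round-off) and is ~13×
faster, which is what makes the evolution experiments tractable without a
GPU.

## In-silico mutagenesis

- **Importance score** of a position: `logit(p_ref) − mean_b logit(p_b)`
  over the four bases (reference included).  Positive means the reference
  base opens chromatin relative to an average base; the four per-base
  scores at a position sum to zero by construction.
- **Windows.** The "most important subsequence" of an example is the
  window with the extreme moving-average importance — maximal for
  model-predicted peaks (its ablation most lowers the output), minimal for
  predicted non-peaks.  Predicted state, not the label, decides the
  direction; states binarize at the validation threshold that maximises
  sensitivity × specificity (candidate cutpoints are midpoints of sorted
  unique scores; ties take the lowest).
- **Knock-in** replaces the central bases of ten fixed low-output non-peak
  backgrounds (lowest mean model output, seeded tie-break) and scores each
  subsequence by its mean output over backgrounds.  **Knock-out** replaces
  the window in place with uniform random bases.
- **Deep random mutagenesis** makes 50/100/200/500 substitutions (distinct
  positions, no back-mutation, alternatives uniform) 1000 times per
  example and reports the fraction of experiments retaining the predicted
  state; the control is the fraction of completely random sequences
  classified as peaks.
- **Effect sizes** are |Δ model output| per substitution by default
  (log-odds scale available); the pooled sample gets a log-normal fit and
  an excess-kurtosis diagnostic on log-effects.

## Greedy evolution (SSWM)

Each generation evaluates every single-base mutant and fixes the one
maximising Σ_t w_t·logit(p_t), w ∈ {−1, 0, +1} per tissue.  Ties break to
the earliest mutant (position-major, bases A<C<G<T); the best mutation is
applied even when its gain is non-positive (flagged), with a
stop-on-no-improvement option.  Sequences containing `N` are rejected.
Trajectories record the chosen mutation and both tissues' outputs per
generation, which is what exposes the "drag" of head-selection on testis
accessibility.  The analysis runs both conditions for a fixed 10
generations (threshold crossing typically happens by generation ~4, so the
dynamics are fully resolved) and compares complete mutation sets
(identity = position + target base) for path overlap.

## Orthology

Liftover interval maps are merged per (source peak, target context) by
single-linkage at ≤ 100 bp nearest-end distance (0 when overlapping;
inclusive), keeping only intervals whose back-map lands within 100 bp of
the original peak.  A peak associated (≤ 100 bp) with another species'
peak or mapped location in *any* genome context is conserved; a peak never
associated anywhere — and with exactly one orthologous location in each
other species — is species-specific; everything else is excluded as
ambiguous.  On a ((in1,in2),out) topology, an outgroup peak associated
with exactly one ingroup implies a parsimony loss on the other ingroup's
lineage; outgroup-only absence is left uncalled.

## The synthetic benchmark

`synthio` fabricates the study conditions: six 4-Mb chromosomes named like
Drosophila arms (so "3L" holdout works verbatim), iid background at GC
0.42, and ≈1,900 peaks (8 per 100 kb, 400 bp wide) against ≈20,000
negative tiles.  The regulatory grammar is four sharp 8-bp
position-probability motifs (85 % consensus probability, ~50 % GC, planted
on the + strand by replacement): activators for head, testis, and both,
plus a shared repressor.  Peaks come in three tissue flavours
(30/30/40 %) and two strengths — peaks destined to stay conserved carry 3
activating instances in their central half; peaks destined to be
lineage-specific carry 2.  Thirty loci per chromosome are "silenced"
decoys (activators + repressors, labelled closed) so a model must learn
repressive grammar.  Divergence rewrites sites at a chosen rate (always to
a different base, no indels — liftover maps stay 1:1 and are emitted
fragmented into ≤ 30-bp-gapped pieces to exercise the merge step);
conserved peaks keep their instances, lost peaks keep one ("poised"
orthologs), and gained peaks appear at background loci.  The conservation
track is +2 at peak-motif bases, −2 at decoy-motif bases, plus Gaussian
noise (σ 0.5) — giving the importance×conservation test a known negative
sign in closed regions.  The three-species scenario draws per-peak
presence patterns with P(all three) = f/(3−2f) and P(specific to each
species) = (1−f)/(3−2f), so each species' peak set is a fraction f
conserved in expectation.

What passing on this benchmark shows — and does not.  The generator makes
the *plumbing and statistics* testable end to end: label construction,
metric code, threshold logic, mutagenesis bookkeeping, orthology calls all
face known ground truth.  It does not emulate real chromatin's redundancy:
planted peaks concentrate their information in 2–3 instances, so ablating
the top importance window costs ~0.10–0.15 AUROC here, where real tissue
data loses almost nothing — the mutational-robustness *profile* (retention
falling smoothly with mutation load, far above the random-sequence
baseline) reproduces, but the knock-out flatness does not, and the package
reports that honestly rather than tuning the generator.  Likewise the
dedicated single-tissue activators give opposing selection a penalty-free
route to tissue-specific accessibility, so the slow-down under opposing
selection appears as a right-shifted distribution of
generations-to-threshold rather than a separated median.  Background is
iid (no dinucleotide structure, repeats, or indels), and motifs are
planted forward-strand only by default (strand-symmetric planting is an
option; one orientation keeps the compact model's filter budget small).

## Standard analysis sizes

One pipeline call (`pipeline.run_study` plus the analysis helpers, which
is exactly what `scripts/acceptance.py` executes) uses: the full example
set for training and test metrics; 80 + 80 held-out examples for
saturation mutagenesis and knock experiments; 16 true-positive peaks ×
1000 experiments × 4 levels for deep mutagenesis; 100 double-negative
seeds × 10 generations × 2 conditions for evolution; a 6 × 3-Mb
three-species scenario (~1,400 ancestral peaks) for orthology; and ~70 windows × the central 200 bp
for the conservation correlation.  The full run takes roughly 15 minutes
on one CPU, about half of which is model training.

## Known limitations

- The numpy network trains small models well but is not a general DL
  framework: no residual connections, no layer norm, single optimizer.
- Importance scores are single-substitution; epistatic attributions
  require the evolution machinery.
- Orthology assumes substitution-only divergence when maps come from
  `synthio`; real halLiftover output needs a one-line conversion to the
  liftover TSV dialect and may violate the 1:1 assumption.
- The Mann–Whitney comparison switches from exact to a tie- and
  continuity-corrected normal approximation above 20 pooled observations.
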