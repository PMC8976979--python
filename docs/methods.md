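# Methods

## Coordinates and labeling

All internal coordinates are 0-based, half-open, on the forward strand;
the 1-based "+1 = TSS" convention of promoter annotation formats is
converted only at the parse/format boundary.  Biological TSS-relative
positions skip zero: +1 is the TSS base, −1 the base immediately
upstream.  Under the default region (249 bases upstream, 50 downstream)
the TSS base sits at window index 249 of a 300-base window, so −33..−23
maps to window indices [216, 227).

A promoter region is extrapolated from each TSS as
`[pos0 − upstream, pos0 + downstream + 1)` on the '+' strand and its
mirror on '−'.  The "−249 to +50" description is interpreted as
249 + 1 + 50 = 300 bases — the only reading consistent with the
251-base (200 + 1 + 50) variant used for the shorter classifier inputs.

A sliding window (default 300/stride 50) is tagged `I` iff **one**
promoter interval overlaps it by at least `min_overlap` (default 250)
contiguous bases; overlaps with different promoters are never summed,
and the boundary is inclusive ("at least 250").  Windows containing a
literal `N` are dropped; soft-masked lowercase bases are uppercased and
retained.  Ambiguity codes other than `N` are degraded to `N` on read so
real genomes parse.  Window sequences are stored as forward-strand text
regardless of the promoter's strand: a scanning classifier reads the
forward strand, while minus-strand promoters still label through genomic
overlap.

Deduplication keeps the first occurrence of each sequence and logs tag
conflicts.  Leak-free splitting makes one master promoter split sized
for the largest model first, samples every smaller model's promoter sets
inside the corresponding master side, then appends per-model negatives;
disjointness is re-verified exhaustively over sequence strings before any
split is returned.

## Synthetic negatives

* **UD** (uniform distribution): selected positions are redrawn
  uniformly from {A, C, G, T}.  A redraw may reproduce the original
  base, so the expected change rate is 3/4 per substituted position —
  composition tests are calibrated accordingly.
* **OPD** (original promoter distribution): selected positions' bases
  are permuted among themselves.  With fraction 1 this is a full
  shuffle, so the base multiset is conserved exactly — a strict,
  per-sequence conservation law, and the property that distinguishes
  OPD from an i.i.d. redraw from the empirical composition.

The substituted fraction is a parameter; the default follows the
segment convention (sequences divided into 32 equal segments, 20
substituted), with a per-position mode available.  Dinucleotide-
preserving shuffles are out of scope.

Genomic negatives come from gene bodies downstream of the first exon,
or from non-promoter windows required to contain a given IUPAC consensus
(e.g. a TATA motif) for motif-matched negative sets.

## Models

All classifiers consume 4×L one-hot matrices in the fixed row order
(A, C, G, T); `N` encodes as an all-zero column.  Four families:

* **cnnprom_tata / cnnprom_nontata** — one convolution bank per filter
  length (defaults 15 and 21), max-pool, ReLU, dense, head.  The TATA
  variant uses fewer filters and a smaller pool (100/pool 2 vs
  200/pool 4); the exact widths beyond the published relations are this
  package's defaults, not literature constants.
* **icnnp** — a 200-filter convolution over the full sequence plus a
  max-pooled context copy, concatenated with one-hot element
  subsequences at fixed TSS-relative locations.  The element table is
  configuration (YAML-loadable); the shipped default places TATA at
  −33..−23 and the initiator at −2..+4 with pool size 3.
* **dprom** — convolutional embedding → max-pool → bidirectional LSTM;
  the full hidden sequence of both directions is flattened into the
  dense head, giving every position a direct gradient path (final-state
  readout trains poorly on motif-position tasks).
* **jaspar_fixed** — convolution filters imported from JASPAR position
  frequency matrices (per-column count→frequency normalization, or
  log₂(f/0.25) log-odds) and frozen; only the head trains, so each
  motif maps to exactly one filter and activations are directly
  interpretable.

Heads: sigmoid (one score, decision threshold 0.5, boundary inclusive)
or softmax (two probabilities, class order non-promoter/promoter,
argmax decision).  Optional per-sample channel normalization after the
convolution (mean/variance over positions) and dropout; normalization
substantially stabilizes CLSTM training by keeping LSTM gate inputs in
range.

The networks run on an in-package reverse-mode autodiff engine over
numpy float64 arrays (convolution via im2col, non-overlapping max
pooling, fused stable BCE/cross-entropy losses, Adam and momentum-SGD).
Gradients of every architecture are validated against central finite
differences in the test suite.  Weight initialization is Glorot-uniform
from a seeded generator; runs are bit-reproducible single-threaded.

## Training and evaluation

Mini-batch training with stratified batches (per-batch class counts
within one of the dataset proportions), learning rate 0.001, at most 50
epochs, early stopping after 5 epochs without validation improvement.
The monitored metric is MCC on a 10% stratified holdout carved from the
training data with the run seed (which metric drives stopping, the CI
construction and per-family batch sizes are this package's explicit
choices, recorded in checkpoints).  Each improvement writes a
self-describing JSON checkpoint (spec + weights + seed); the best is
restored at the end.  A non-finite loss aborts with a diagnostic.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), and MCC.
`I` is the positive class.  Any zero denominator reports 0 for the
affected metric together with an explicit `undefined` flag — silent
NaNs would poison cross-testing matrices.  Cross-validation is
stratified k-fold (default 10) with a fresh model per fold; fold-score
confidence intervals use Student-t with k−1 degrees of freedom at the
99% level, recorded in the report so alternative constructions can be
compared.  Class rebalancing: undersampling keeps at most `ratio`
non-promoters per promoter; oversampling duplicates promoters (with
replacement, seeded) until the O:I ratio is at most `ratio`.
Cross-testing evaluates every model on every dataset's full contents;
input-length mismatches become explicit `incompatible` cells.

## Synthetic study conditions

The generator draws an i.i.d. background at configurable GC content
(default 0.41, human-like), plants non-overlapping 300-base promoter
regions with motifs at fixed TSS-relative offsets — defaults TATAAA at
−31 and a TCAKTY initiator at −2, IUPAC letters resolved per promoter —
on both strands (minus-strand regions are written as reverse
complements), overwrites N-blocks last, and returns the genome, the TSS
annotations and the ground-truth intervals.  It emulates the positional
anatomy of core promoters, not repeat structure, isochores or Markov
dependence of real genomes: passing tests demonstrate that the
machinery is correct and that the architectures can learn planted
positional signals, not that they perform comparably on real
chromosomes.

The frozen worked example (2,000 bases, two promoters, one per strand,
one N-block) ships with a golden window file computed once by an
independent brute-force per-base overlap scan.

### Problem sizes of the canned experiments

The learnability smoke test trains the CLSTM on 1,000 planted-motif
windows (500/500) and evaluates on 500; with motifs enabled the held-out
MCC is expected ≥ 0.9, and with motifs disabled (negative control) the
same pipeline must stay within ±0.1 of chance.  At this sample size the
task is nearly linearly separable — the test suite fits a
position-specific logistic-regression reference on the same conditions
and requires MCC ≥ 0.95 of it — so the bar tests the training loop, not
the task's ceiling.

The imbalance experiment trains a CNN on 600 TSS-centred planted
windows — mirroring how literature models train on curated,
TSS-centred promoter databases — and evaluates it, fixed, on
sliding-window benchmarks from a fresh 400-kb synthetic chromosome at
non-promoter:promoter ratios 1, 10 and 100 (promoter windows held
constant, the non-promoter pool subsampled with a seed).  Sensitivity
is low by construction: benchmark windows are shifted by up to ±50
bases relative to the training alignment, and a positionally strict
model misses shifted promoters — the same strict-positional behaviour
the sliding-window design is meant to expose.  Since the model's
false-positive rate on genomic windows is fixed, precision falls
roughly tenfold per tenfold ratio increase.

## Numerical and degenerate-input choices

* Sigmoid decisions are inclusive at the 0.5 boundary.
* Max pooling drops the trailing remainder when the length is not a
  pool multiple; all derived widths are pure functions of the
  configuration, never of the data.
* Empty genomes shorter than one window yield an empty dataset with a
  warning; out-of-bounds extraction raises instead of clipping.
* k-mer reconstruction validates the k−1 overlap of consecutive tokens
  and names the first offending token.
* All sampling, splitting, initialization and generation is seeded;
  seeds are recorded in dataset metadata, checkpoints and CLI manifests.

## Known limitations

Approximate (alignment-based) promoter mapping is out of scope — the
exact-match mapper defines the interval-producing interface an external
aligner could feed.  Annotation sources are supported as URL templates
plus digest verification only; nothing fetches from the network.
Transformer models are not implemented; only the k-mer token interchange
format for such external tools is.  Real-genome window totals depend on
assembly and annotation details that the synthetic conditions do not
model.
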