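# Methods

## Problem and coordinate model

The unit of prediction is a 200-bp genomic bin on a 50-bp sliding grid
(0-based, half-open coordinates everywhere, matching BED and friends).
Labels come from two ChIP-Seq peak sets per cell type: bins overlapping a
*conservative* (reproducibility-filtered) peak by at least 1 bp are
bound (B); bins overlapping only a *relaxed* peak are ambiguous (A) and
take no part in training or evaluation; everything else is unbound (U).
The ≥1-bp overlap threshold is the simplest consistent reading of
"overlap" and is exposed as a parameter. Bins overlapping a blacklist
region are dropped from training and forced to score 0 at prediction
time. Each bin is expanded symmetrically by a flank (default 400 bp →
1000-bp input). At chromosome ends the region is clipped and the missing
span recorded as padding; padded rows are all-zero in every feature
channel, preserving a fixed input length.

## Features

Per strand, an L × C block with fixed channel order A, C, G, T,
uniqueness, accessibility [, conservation, CpG-island]:

- **one-hot sequence** — N and padded rows are all-zero;
- **35-mer uniqueness** (mappability) — per position, the inverse of the
  genome-wide occurrence count of the 35-mer starting there, counting
  both strands: unique → 1, 2–4 copies → 1/count, more than four → 0.
  The final k−1 positions of each chromosome score 0. On synthetic
  genomes this is computed exactly by hashing every k-mer;
- **accessibility** — per-base coverage scaled by a single constant so
  the genome-wide mean is 1 (RPGC-style); an all-zero track is left
  unchanged;
- optional **conservation** (values in [0,1], taken as input) and
  **CpG-island** channel: a window (default 200 bp, centered) is CGI
  when N_CpG·L/((N_C+N_G)/2)² > 0.6 *and* (N_C+N_G)/L > 0.5; zero GC
  short-circuits to 0.

The reverse-complement block swaps the A/T and C/G columns and reverses
all channels along the length axis; scalar tracks are strand-agnostic
and are only reversed.

The non-sequential vector has exactly 14 entries: six binary annotation
flags (coding, intron, promoter, 5′-UTR, 3′-UTR, CpG island — the UTRs
are separate flags, the only reading that yields six) and eight
expression principal-component scores per cell type. PCA treats each
cell type as one observation over genes, centers without variance
scaling, and fixes each component's sign by making its
largest-magnitude loading positive, so scores are identical across
platforms and runs; with n cell types only n−1 components exist and the
rest are zero-padded. Whether to log-transform TPMs first is genuinely
open; a `log_transform` flag defaults to off.

## Network

One weight-shared trunk per strand (Siamese): a valid 1-D convolution
(defaults: 64 filters, width 34, ReLU), max-pooling (width 10), and a
Bi-LSTM (32 units per direction) whose forward and backward hidden
states are concatenated. The LSTM recurrence is the standard gated
update: sigmoid forget/input/output gates over [h_{t−1}, x_t], tanh
candidate state, C_t = f⊙C_{t−1} + i⊙C̃_t, h_t = o⊙tanh(C_t); forget-gate
biases initialize at 1.

Two branches read the trunk output h (l positions × r features):

- **single attention**: e = M·h + bias with M an l × l matrix; softmax
  over positions within each feature column; the column weights are
  averaged to one ᾱᵢ per position (the divisor is the feature width, per
  the averaging description); output zᵢᵣ = hᵢᵣ·ᾱᵢ. M is initialized as
  identity plus small noise so that early in training the attention
  profile reflects local content rather than an arbitrary fixed mixture
  of positions — this measurably helps at small data scale.
- **pairwise attention**: sinusoidal positional encodings
  (PE(pos,2i)=sin(pos/10000^{2i/d}), cos at odd columns) are added to h;
  Q, K, V are feature-axis projections (the only shape-consistent
  reading of the stated dimensions); attention = row-softmax of
  QKᵀ/√d_k; Z = attention·V. The attention matrix is retained for
  interpretation.

Each branch flattens its output, concatenates the 14-long non-sequential
vector, and scores through one ReLU dense layer and a 1-unit sigmoid.
Strand scores merge first (mean by default; max available), then branch
scores. With mean merges the architecture is exactly symmetric under
swapping the two strand inputs, which the tests exploit. All softmaxes
use max-subtraction; the forward pass is deterministic at inference
(dropout only acts during training).

Everything runs on a small reverse-mode autodiff core over NumPy
(`attnbind.autodiff`): a tape of array nodes with hand-written adjoints
for matmul (broadcast-aware), conv1d (im2col forward, column-scatter
backward), max-pooling (argmax routing), softmax, slicing and the
pointwise maps. Gradients of every primitive and of the assembled
network are verified against central finite differences in the suite.

## Training

Bound bins are a tiny minority, so each epoch trains on all positives
mixed with freshly drawn negatives — `ratio` × the positive count,
without replacement within the epoch, deterministic given (seed, epoch).
For factors with very many peaks, `peak_resample` mode instead draws one
uniformly placed 200-bp window per peak per epoch. Ambiguous and
blacklisted bins are never sampled. The loss is binary cross-entropy
under Adam (default learning rate 1e-3). When `balance_loss` is on (the
default), the positive-class term is weighted by `ratio`, so increasing
negative coverage per epoch does not shift the score calibration away
from a balanced prior — this keeps the 0.5 positive threshold used by
the interpretation stage meaningful. Training stops at the epoch cap
(default 60) or when validation auPRC has not improved — strict increase
beyond 1e-5, counted from the best epoch — for five consecutive epochs;
the best-validation weights are restored. Among candidate checkpoints,
selection is argmax validation auPRC with ties to the earliest.

## Evaluation

auROC (trapezoidal; equal to the Mann–Whitney probability with ties at
½), auPRC (interpolation-free step sum), and recall at 50%/10% FDR
(maximum recall over thresholds with precision ≥ 1−FDR; 0 when none
qualifies). These are computed via scikit-learn, whose definitions
coincide with the above; the test suite re-derives every value by
exhaustive threshold enumeration on small instances. The unified score
is Σ ln(r/6) over the four per-measure ranks (smaller is better; ties
get average ranks). Published per-target summaries are often printed on
the r/6 scale instead, so `rank_fraction` (mean r/6) is provided
alongside; neither convention is silently "corrected" into the other.

## Interpretation

Attention positions are coarser than the input: with conv width K
(stride 1) and pool width p, attention position a's receptive field is
input rows [ap, ap+p+K−2], so traces carry the affine map genomic bp =
origin + a·p with origin at the receptive-field center. Because pooling
drops trailing convolution outputs, the reverse-complement grid is
offset from the forward grid by L−1−2·offset−(l−1)·p bp; RC traces are
reversed along the position axis and carry their own origin, and strand
averaging aligns the two grids by the integer position shift. Saliency
is the input gradient of the final score, reduced per position by the
maximum absolute value over channels (L2 selectable), RC reversed the
same way.

Motif localization follows the high-attention-window procedure: among
bins predicted positive (score > 0.5) whose accessibility profile has no
dominant spike (max/mean < 15 within the region; zero-mean regions are
dropped), take the argmax (leftmost on ties) of the pairwise branch's
attention column sums (single branch selectable), map it to genomic bp,
and cut a 20-bp window centered there (clipped to the region). Windows
are written as BED + FASTA and scored by an internal PWM scanner: best
log₂-odds over all offsets and both strands against a uniform
background, zero probabilities floored at 1e-3. Whether "around each
coordinate" means centered or left-anchored is unstated; centered here.
Attention-signal association pools (attention, fold-change) pairs across
bins — the track averaged over each position's window — z-scores both,
and reports Pearson and Spearman coefficients, with a one-sided
permutation test for positivity.

## Synthetic data

The generator encodes the causal structure the method assumes: binding
requires a sequence motif *and* open chromatin. On a random genome
(default 200 kb as three ~66.6-kb chromosomes, GC 0.5) it plants, with
≥1.5-kb separation and 1-kb end margins: 20 *bound* sites (a PWM motif
instance plus accessibility), 20 accessible-but-motif-free decoys, and
20 motif-but-closed decoys. The PWM assigns the consensus base
probability s + (1−s)/4 (sharpness s, default 0.95 over a 10-bp
consensus). Cell types (default two) share the genome but each bound
site is accessible in a cell type with probability 0.75 — the
cross-cell-type signal the predictor must generalize over.
Accessibility tracks are Gaussian bumps (height 10, sd 40 bp) on a
baseline of 1 with mild Gaussian noise (sd 0.05, clipped at 0); ChIP
fold-change bumps are height 10, sd 75 bp at bound-and-open sites.
Conservative peaks are ±100 bp around each open bound site; relaxed
peaks add weak peaks at a quarter of the accessible decoys, which yields
ambiguous bins. Labels are derived through the same binning/labeling
code the real pipeline uses; an optional label-noise rate flips B↔U.
Everything — placement, sequences, noise, expression matrix — is drawn
from one seeded generator, and emitted files (FASTA, narrowPeak,
bedGraph, label TSV, expression TSV, BED annotations, manifest with a
config hash) are byte-identical across runs of the same seed.

What the fixture does *not* emulate: read-level sequencing noise,
fragment-length effects, DNase cut bias, mappability structure of real
repeats, or motif families with soft syntax. Passing here shows the
pipeline's machinery and the architecture's ability to combine sequence
with accessibility at small scale — not performance on real genomes.

## Desk-scale benchmark configuration

The bundled benchmark (`pipeline.run_synthetic_benchmark`) trains on
cellA over chrA+chrB, early-stops on cellA/chrC, and evaluates the fully
held-out cellB over chrB+chrC (chrC's labels are never trained on;
cellB is never seen at all). The small model uses 600-bp input regions
(flank 200; beyond ~600 bp the added flanks contribute little), 16
conv filters of width 12, pool 10, 8 LSTM units per direction,
d_k = d_v = 8, dense width 16, learning rate 0.01, 20 epochs, batch 16,
and negative ratio 8 with the balance-weighted loss. With the default
fixture this reaches held-out auPRC ≈ 0.55 (three-seed mean) against an
accessibility-only logistic baseline of ≈ 0.47 at prevalence ≈ 0.02,
with auROC ≈ 0.99.

## Known limitations

- Motif *localization* by attention is weak at this data scale: after 20
  epochs on ~70 positive bins, the attention argmax lands within the
  ±14 bp needed for a 20-bp window to overlap a planted 10-bp motif in
  only ~20–40% of true-positive bins (and longer training plateaus below
  50%), while roughly half of score>0.5 candidate bins are false
  positives containing no motif. Sharp, reliable attention-to-motif
  correspondence of the kind reported on full-genome training sets
  should not be expected from the 200-kb fixture; the extraction
  machinery itself is verified separately with a hand-constructed
  motif-attending model, and the attention-vs-fold-change correlation is
  reliably positive (permutation p < 0.01).
- The uniqueness track is exact hashing — appropriate for synthetic
  genomes, quadratic-memory-hostile for real ones (use published
  mappability tracks there).
- Recall at 10% FDR is typically 0 at desk scale; the score ranking is
  good, but absolute precision at very strict thresholds needs more
  training data than the fixture provides.
- The autodiff core is single-threaded NumPy; it is sized for the
  desk-scale configurations, not for full-genome training.
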