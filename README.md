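# attnbind

Cross-cell-type transcription-factor (TF) binding-site prediction with a
dual-attention convolutional recurrent network, together with the full
surrounding pipeline: genome binning and labeling from ChIP-Seq peaks,
sequence/mappability/accessibility feature encoding, iterative-sampling
training, the four standard benchmark metrics, attention-based
interpretation, and a seeded synthetic-genome generator that makes every
stage testable offline on a laptop.

## Who this is for

Computational biologists who want to predict where a TF binds in a cell
type with no ChIP-Seq data, using only the genome sequence and that cell
type's chromatin accessibility (DNase-Seq) profile — and who want to
inspect *why* the model calls a site bound, via its attention weights.

## The model

The genome is tiled into 200-bp bins on a 50-bp grid. A bin is **B**
(bound) when it overlaps a reproducible (IDR-passing) ChIP-Seq peak,
**A** (ambiguous) when it only overlaps a relaxed peak, and **U**
(unbound) otherwise; ambiguous bins are excluded throughout. Each bin is
expanded by 400 bp per side to a 1000-bp input region and encoded, for
both the forward and the reverse-complement strand, as an L × (4+1+1)
block: one-hot sequence, 35-bp k-mer uniqueness (mappability), and
1×-normalized accessibility coverage (optional conservation and CpG-island
channels extend this). A length-14 vector of six genomic-annotation flags
plus eight expression principal components is fused at the dense layer.

Both strands pass through one weight-shared (Siamese) trunk — 1-D
convolution, max-pooling, Bi-LSTM — and two attention branches:

- **single attention**: e = M·h + bias, softmax over positions per
  feature column, averaged to one weight ᾱᵢ per position,
  zᵢᵣ = hᵢᵣ·ᾱᵢ;
- **pairwise attention**: Z = softmax(QKᵀ/√d_k)·V with sinusoidal
  positional encodings added to the input (d_k = d_v = 64 by default).

Each branch ends in a dense + sigmoid head; strand scores are merged
(mean by default), then branch scores. Training mixes all positive bins
with freshly resampled negatives every epoch (Adam, binary cross-entropy,
up to 60 epochs, early stopping on validation auPRC with patience 5).
Evaluation uses auROC, auPRC, recall at 50%/10% FDR and the rank-based
unified score Σ ln(r/6).

The network (and its gradient machinery) is implemented on a small NumPy
reverse-mode autodiff core (`attnbind.autodiff`), so the whole package
runs anywhere NumPy does.

## Worked example

Simulate the default 200-kb fixture (three chromosomes, 20 bound sites
whose planted motif *and* accessibility peak must coincide, plus
accessible-but-motif-free and motif-but-closed decoys, two cell types
with different accessible subsets), train on one cell type, and score the
held-out cell type:

```python
from attnbind.evaluation import ScoredLabels, evaluate_all
from attnbind.pipeline import run_synthetic_benchmark
from attnbind.simulate import SimulationConfig, simulate

truth = simulate(SimulationConfig(seed=7))
(result,) = run_synthetic_benchmark(truth, model_seeds=(0,))
metrics = evaluate_all(ScoredLabels(result.test_scores, result.test_labels.astype(int)))
print(f"held-out cell type: prevalence {result.prevalence:.4f}")
for name, value in metrics.items():
    print(f"{name:>18}: {value:.3f}")
print(f"  dnase-only auPRC: {result.baseline_auprc:.3f}")
```

Output (about a minute on one CPU):

```
held-out cell type: prevalence 0.0215
             auroc: 0.988
             auprc: 0.549
  recall_at_50_fdr: 0.839
  recall_at_10_fdr: 0.000
  dnase-only auPRC: 0.467
```

Reading: only ~2% of held-out bins are bound, yet the model ranks them
almost perfectly by auROC (0.988) and reaches an auPRC of 0.549 —
comfortably above both chance (0.0215) and an accessibility-only logistic
baseline (0.467), i.e. the network is using the sequence motif, not just
open chromatin. Recall at 50% FDR says 84% of bound bins are recovered
while keeping at least half of all calls correct; the stricter 10% FDR
bar is not met at this desk scale.

The same workflow is available from the shell:

```bash
attnbind simulate --seed 7 --out sim/
attnbind train --data sim/ --cell cellA --train-chroms chrA,chrB \
               --val-chrom chrC --seed 0 --out model.npz --metrics history.tsv
attnbind predict --data sim/ --cell cellB --chroms chrC \
                 --checkpoint model.npz --out preds.tsv
attnbind evaluate --predictions preds.tsv --labels sim/labels.tsv --cell cellB
```

Interpretation utilities live in `attnbind.interpretation`: per-region
attention traces mapped back to genome coordinates, gradient saliency,
20-bp motif-window extraction under attention peaks, an internal PWM
scanner (JASPAR/MEME readers included), and attention-vs-fold-change
correlation with a permutation test.

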