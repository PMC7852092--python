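"""Training scheme: per-epoch negative resampling, Adam + binary
cross-entropy, auPRC-based early stopping and model selection.

Genome-scale binding labels are overwhelmingly negative, so each epoch
trains on *all* positive (B) bins mixed with a fresh, equally-sized (by
default) random draw of unbound (U) bins; ambiguous (A) and
blacklist-overlapping bins never enter an epoch.  For factors with very
many peaks the positive set can instead be resampled each epoch as one
random 200-bp window per ChIP-Seq peak (``peak_resample``).  Training
stops at the epoch cap (default 60) or when validation auPRC has not
improved for five consecutive epochs, and the best-validation weights are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import autodiff as ad
from .evaluation import auprc, auroc, ScoredLabels
from .features import FeatureAssembler
from .intervals import GenomicBin, IntervalSet, expand_bin
from .model import DualAttentionModel, ModelConfig, bce_loss


@dataclass
class EpochSample:
    positives: list[GenomicBin]
    negatives: list[GenomicBin]
    epoch_index: int
    seed: int


@dataclass
class TrainState:
    epoch: int = 0
    best_val_auprc: float = -np.inf
    best_epoch: int = -1
    epochs_since_improvement: int = 0
    history: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def sample_epoch(
    bins: Sequence[GenomicBin],
    mode: str = "all_positives",
    peaks: IntervalSet | None = None,
    ratio: float = 1.0,
    seed: int = 0,
    epoch_index: int = 0,
    bin_size: int = 200,
) -> EpochSample:
    """Build one epoch's training mixture.

    ``all_positives``: every B-labeled bin; ``peak_resample``: one
    uniformly placed ``bin_size`` window inside each peak.  Negatives are
    ``ratio`` times the positive count, drawn without replacement from the
    U bins, re-drawn each epoch.  Deterministic given (seed, epoch_index).
    """
    rng = np.random.default_rng([seed, epoch_index])
    if any(b.label == "A" for b in bins):
        raise ValueError("ambiguous bins must be excluded before sampling")
    u_bins = [b for b in bins if b.label == "U"]
    if mode == "all_positives":
        positives = [b for b in bins if b.label == "B"]
    elif mode == "peak_resample":
        if peaks is None:
            raise ValueError("peak_resample mode requires a peak set")
        positives = []
        for rec in peaks.sorted_records():
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            span = max(0, end - start - bin_size)
            s = start + int(rng.integers(0, span + 1))
            positives.append(GenomicBin(chrom, s, s + bin_size, "B"))
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    if not positives:
        raise ValueError("no positive bins: target is untrainable")
    n_neg = max(1, int(ratio * len(positives)))
    n_neg = min(n_neg, len(u_bins))
    idx = rng.choice(len(u_bins), size=n_neg, replace=False)
    negatives = [u_bins[i] for i in sorted(idx)]
    return EpochSample(positives, negatives, epoch_index, seed)


def early_stop_epoch(
    val_metrics: Sequence[float],
    patience: int = 5,
    tol: float = 1e-5,
    max_epochs: int = 60,
) -> int:
    """Number of epochs a run with this validation trace would execute.

    Improvement means a strict increase (beyond ``tol``) over the best
    value so far; after ``patience`` consecutive non-improving epochs the
    run stops, otherwise it runs to ``max_epochs``.
    """
    best = -np.inf
    since = 0
    for epoch, v in enumerate(val_metrics[:max_epochs], start=1):
        if v > best + tol:
            best = v
            since = 0
        else:
            since += 1
            if since >= patience:
                return epoch
    return min(len(val_metrics), max_epochs)


def select_model(candidates: Sequence[tuple[dict, float]]) -> dict:
    """Pick the weights with the best validation auPRC; ties go to the
    earliest candidate."""
    if not candidates:
        raise ValueError("no candidate models")
    best_i = 0
    for i, (_, v) in enumerate(candidates):
        if v > candidates[best_i][1]:
            best_i = i
    return candidates[best_i][0]


class Adam:
    """Adam optimizer over the model's named parameter tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class RegionDataset:
    """Materialised model inputs for a fixed list of bins."""

    block_fwd: np.ndarray  # (n, L, C)
    block_rc: np.ndarray
    nonseq: np.ndarray  # (n, 14)
    labels: np.ndarray  # (n,) 0/1
    bins: list[GenomicBin]


def build_dataset(
    bins: Sequence[GenomicBin],
    assembler: FeatureAssembler,
    nonseq_fn,
    flank: int,
) -> RegionDataset:
    """``nonseq_fn(bins) -> (n, 14)`` supplies the fused non-sequential
    vectors (annotation flags + expression PCs)."""
    n = len(bins)
    L = (bins[0].end - bins[0].start) + 2 * flank if n else 0
    C = assembler.n_channels
    bf = np.zeros((n, L, C))
    br = np.zeros((n, L, C))
    for i, b in enumerate(bins):
        region = expand_bin(b, flank, assembler.chrom_lengths[b.chrom])
        fwd, rc = assembler.block_pair(region)
        bf[i], br[i] = fwd.matrix, rc.matrix
    labels = np.array([1.0 if b.label == "B" else 0.0 for b in bins])
    ns = nonseq_fn(list(bins))
    return RegionDataset(bf, br, ns, labels, list(bins))


def fit(
    model: DualAttentionModel,
    train_bins: Sequence[GenomicBin],
    val_dataset: RegionDataset,
    assembler: FeatureAssembler,
    nonseq_fn,
    peaks: IntervalSet | None = None,
    verbose: bool = False,
) -> TrainState:
    """Train with per-epoch resampling and patience-5 early stopping.

    ``train_bins`` must already exclude ambiguous and blacklisted bins and
    held-out chromosomes; validation bins must come from a disjoint
    chromosome.  Returns the training history; the model is left holding
    the best-validation weights.
    """
    cfg = model.config
    if len(val_dataset.labels) == 0:
        raise ValueError("empty validation set")
    state = TrainState()
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_weights = model.get_weights()
    for epoch in range(cfg.epochs):
        sample = sample_epoch(
            train_bins, cfg.positive_mode, peaks, cfg.negative_ratio,
            seed=cfg.seed, epoch_index=epoch, bin_size=cfg.bin_size,
        )
        data = build_dataset(
            sample.positives + sample.negatives, assembler, nonseq_fn,
            cfg.flank,
        )
        order = rng.permutation(len(data.labels))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            scores = model.forward(
                data.block_fwd[sel], data.block_rc[sel], data.nonseq[sel],
                train=True, rng=rng,
            )
            pos_w = cfg.negative_ratio if cfg.balance_loss else 1.0
            loss = bce_loss(scores, data.labels[sel], pos_weight=pos_w)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_scores = model.predict(
            val_dataset.block_fwd, val_dataset.block_rc, val_dataset.nonseq
        )
        sl = ScoredLabels(val_scores, val_dataset.labels.astype(int))
        val_auprc = auprc(sl)
        val_auroc = auroc(sl)
        state.epoch = epoch + 1
        state.history.append(
            {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
             "val_auroc": val_auroc, "val_auprc": val_auprc}
        )
        if verbose:
            print(f"epoch {epoch + 1}: loss={np.mean(losses):.4f} "
                  f"val_auprc={val_auprc:.4f}")
        if val_auprc > state.best_val_auprc + cfg.patience_tol:
            state.best_val_auprc = val_auprc
            state.best_epoch = epoch + 1
            state.epochs_since_improvement = 0
            best_weights = model.get_weights()
        else:
            state.epochs_since_improvement += 1
            if state.epochs_since_improvement >= cfg.patience:
                break
    model.set_weights(best_weights)
    return state


def memorize(
    model: DualAttentionModel, data: RegionDataset, max_epochs: int = 200,
    target_loss: float = 0.1,
) -> list[float]:
    """Fit a fixed batch until BCE drops below ``target_loss`` (sanity
    check that the network and optimizer can learn at all)."""
    opt = Adam(model.params, lr=model.config.learning_rate)
    losses = []
    for _ in range(max_epochs):
        scores = model.forward(data.block_fwd, data.block_rc, data.nonseq)
        loss = bce_loss(scores, data.labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        if losses[-1] < target_loss:
            break
    return losses


def dnase_logistic_baseline(
    train: RegionDataset, test: RegionDataset, seed: int = 0
) -> np.ndarray:
    """Accessibility-only logistic-regression baseline.

    Features per bin: mean and max accessibility over the bin and over the
    whole input region (channel 5 of the feature block).
    """

    def feats(ds: RegionDataset) -> np.ndarray:
        acc = ds.block_fwd[:, :, 5]
        L = acc.shape[1]
        bin_size = ds.bins[0].end - ds.bins[0].start
        lo = (L - bin_size) // 2
        core = acc[:, lo : lo + bin_size]
        return np.column_stack(
            [acc.mean(1), acc.max(1), core.mean(1), core.max(1)]
        )

    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(feats(train), train.labels)
    return clf.predict_proba(feats(test))[:, 1]
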