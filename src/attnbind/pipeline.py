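"""Glue between the synthetic fixture / on-disk inputs and the trainable
dataset: per-cell-type feature assemblers, fused non-sequential vectors,
and the train/validation/test bin splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .features import (
    ANNOTATION_CATEGORIES,
    FeatureAssembler,
    annotation_vector,
    expression_pcs,
    uniqueness_track,
)
from .intervals import GenomicBin, IntervalSet, apply_blacklist
from .simulate import SyntheticTruth


def normalize_tracks(tracks: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """1x-normalize a multi-chromosome coverage track with one shared
    scale (genome-wide mean becomes 1)."""
    total_len = sum(len(t) for t in tracks.values())
    total = sum(float(np.sum(t)) for t in tracks.values())
    if total == 0:
        return {c: np.asarray(t, dtype=np.float64).copy() for c, t in tracks.items()}
    scale = total_len / total
    return {c: np.asarray(t, dtype=np.float64) * scale for c, t in tracks.items()}


def make_nonseq_fn(
    annotation_sets: Mapping[str, IntervalSet] | None,
    expression_vec: np.ndarray,
) -> Callable[[Sequence[GenomicBin]], np.ndarray]:
    """Builds the per-bin length-14 fused vector: 6 annotation flags plus
    8 expression PCs (annotation flags are zero when no sets given)."""

    def fn(bins: Sequence[GenomicBin]) -> np.ndarray:
        rows = []
        for b in bins:
            if annotation_sets is None:
                ann = np.zeros(len(ANNOTATION_CATEGORIES))
            else:
                ann = annotation_vector(b, annotation_sets)
            rows.append(np.concatenate([ann, expression_vec]))
        return np.asarray(rows)

    return fn


@dataclass
class CellData:
    """Everything needed to train or score one cell type."""

    cell: str
    assembler: FeatureAssembler
    nonseq_fn: Callable[[Sequence[GenomicBin]], np.ndarray]
    bins_by_chrom: dict[str, list[GenomicBin]]  # A + blacklist dropped

    def bins(self, chroms: Sequence[str]) -> list[GenomicBin]:
        out: list[GenomicBin] = []
        for c in chroms:
            out.extend(self.bins_by_chrom[c])
        return out


def desk_scale_model_config(seed: int = 0, **overrides) -> "ModelConfig":
    """The package's small CPU configuration: 600-bp input regions
    (ranges of 600 bp and above carry essentially the full signal), a
    16-filter width-12 convolution, pool 10, 8 LSTM units per direction,
    d_k = d_v = 8, and 20 epochs with 1:8 negative sampling under the
    balance-weighted loss."""
    from .model import ModelConfig

    base = dict(
        flank=200, conv_filters=16, conv_width=12, pool_size=10,
        lstm_units=8, attention_dk=8, attention_dv=8, dense_units=16,
        dropout=0.0, learning_rate=0.01, negative_ratio=8.0,
        epochs=20, batch_size=16, seed=seed,
    )
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class BenchmarkResult:
    """One trained model plus its held-out-cell evaluation."""

    model: "DualAttentionModel"
    train_state: "TrainState"
    test_scores: np.ndarray
    test_labels: np.ndarray
    test_bins: list[GenomicBin]
    auprc: float
    baseline_auprc: float
    prevalence: float


def run_synthetic_benchmark(
    truth: SyntheticTruth,
    model_seeds: Sequence[int] = (0, 1, 2),
    train_cell: str = "cellA",
    test_cell: str = "cellB",
    train_chroms: Sequence[str] = ("chrA", "chrB"),
    val_chrom: str = "chrC",
    test_chroms: Sequence[str] = ("chrB", "chrC"),
    uniqueness: Mapping[str, np.ndarray] | None = None,
    verbose: bool = False,
) -> list[BenchmarkResult]:
    """The package's cross-cell-type desk-scale benchmark.

    Trains one model per seed on ``train_cell`` over ``train_chroms``,
    early-stops on ``val_chrom`` of the same cell, and scores the fully
    held-out ``test_cell`` (whose accessible-site subset differs) over
    ``test_chroms``; ``val_chrom``'s labels are never trained on.  Also
    fits the accessibility-only logistic baseline on the same training
    bins for comparison.
    """
    from .evaluation import ScoredLabels, auprc as _auprc
    from .model import DualAttentionModel
    from .training import build_dataset, dnase_logistic_baseline, fit

    if uniqueness is None:
        uniqueness = uniqueness_track(truth.genome)
    tr = prepare_cell(truth, train_cell, uniqueness)
    te = prepare_cell(truth, test_cell, uniqueness)
    results = []
    val = build_dataset(tr.bins([val_chrom]), tr.assembler, tr.nonseq_fn,
                        desk_scale_model_config().flank)
    test_bins = te.bins(list(test_chroms))
    test = build_dataset(test_bins, te.assembler, te.nonseq_fn,
                         desk_scale_model_config().flank)
    train_ds = build_dataset(tr.bins(list(train_chroms)), tr.assembler,
                             tr.nonseq_fn, desk_scale_model_config().flank)
    base_scores = dnase_logistic_baseline(train_ds, test)
    base_ap = _auprc(ScoredLabels(base_scores, test.labels.astype(int)))
    for seed in model_seeds:
        cfg = desk_scale_model_config(seed=seed)
        model = DualAttentionModel(cfg)
        state = fit(model, tr.bins(list(train_chroms)), val, tr.assembler,
                    tr.nonseq_fn, verbose=verbose)
        scores = model.predict(test.block_fwd, test.block_rc, test.nonseq)
        ap = _auprc(ScoredLabels(scores, test.labels.astype(int)))
        results.append(BenchmarkResult(
            model=model, train_state=state, test_scores=scores,
            test_labels=test.labels, test_bins=test_bins, auprc=ap,
            baseline_auprc=base_ap, prevalence=float(test.labels.mean()),
        ))
    return results


def prepare_cell_from_files(
    datadir,
    cell: str,
    uniqueness: Mapping[str, np.ndarray] | None = None,
) -> CellData:
    """Build a :class:`CellData` from a simulated-dataset directory
    (genome.fa, <cell>.dnase.bedGraph, labels.tsv, blacklist.bed,
    annotations/<category>.bed, expression.tsv)."""
    from pathlib import Path

    import pandas as pd

    from . import io as aio
    from .intervals import bins_from_label_frame, read_bed, read_label_tsv

    d = Path(datadir)
    genome = aio.read_fasta(d / "genome.fa")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    if uniqueness is None:
        uniqueness = uniqueness_track(genome)
    accessibility = normalize_tracks(
        aio.read_bedgraph(d / f"{cell}.dnase.bedGraph", chrom_lengths)
    )
    assembler = FeatureAssembler(genome, uniqueness, accessibility)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    pcs = expression_pcs(expression)
    ann_dir = d / "annotations"
    annotations = None
    if ann_dir.is_dir():
        annotations = {
            name: read_bed(ann_dir / f"{name}.bed")
            for name in ANNOTATION_CATEGORIES
        }
    nonseq_fn = make_nonseq_fn(annotations, pcs[cell])
    frame = read_label_tsv(d / "labels.tsv")
    usable = [b for b in bins_from_label_frame(frame, cell) if b.label != "A"]
    bl_path = d / "blacklist.bed"
    if bl_path.exists():
        usable = apply_blacklist(usable, read_bed(bl_path), mode="drop")
    bins_by_chrom: dict[str, list[GenomicBin]] = {c: [] for c in genome}
    for b in usable:
        bins_by_chrom[b.chrom].append(b)
    return CellData(cell, assembler, nonseq_fn, bins_by_chrom)


def prepare_cell(
    truth: SyntheticTruth,
    cell: str,
    uniqueness: Mapping[str, np.ndarray] | None = None,
) -> CellData:
    """Assemble one synthetic cell type's features and usable bins.

    Pass a precomputed ``uniqueness`` map when preparing several cell
    types of the same genome (it only depends on the sequence).
    """
    if uniqueness is None:
        uniqueness = uniqueness_track(truth.genome)
    accessibility = normalize_tracks(truth.accessibility[cell])
    assembler = FeatureAssembler(truth.genome, uniqueness, accessibility)
    pcs = expression_pcs(truth.expression)
    nonseq_fn = make_nonseq_fn(truth.annotations, pcs[cell])
    usable = [b for b in truth.labels[cell] if b.label != "A"]
    usable = apply_blacklist(usable, truth.blacklist, mode="drop")
    bins_by_chrom: dict[str, list[GenomicBin]] = {c: [] for c in truth.genome}
    for b in usable:
        bins_by_chrom[b.chrom].append(b)
    return CellData(cell, assembler, nonseq_fn, bins_by_chrom)
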