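"""Genome binning, three-way bin labeling, blacklist handling and flank
expansion.

All coordinates are 0-based half-open (BED convention).  A *bin* is a
fixed-width window (default 200 bp) on a sliding grid (default 50 bp step);
it is the unit of labeling and prediction.  A bin is labeled ``B`` (bound)
when it overlaps a reproducible (IDR-passing, "conservative") ChIP-Seq
peak, ``A`` (ambiguous) when it only overlaps a relaxed peak, and ``U``
(unbound) otherwise.  Ambiguous bins are excluded from training and
evaluation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BIN_SIZE = 200
BIN_STEP = 50
FLANK = 400

Label = Literal["B", "U", "A", "unlabeled"]


@dataclass(frozen=True)
class GenomicBin:
    """A labeled fixed-width window on a chromosome."""

    chrom: str
    start: int
    end: int
    label: Label = "unlabeled"
    cell_type: str | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class IntervalSet:
    """A set of genomic intervals (peaks, blacklist, annotation...).

    ``records`` are ``(chrom, start, end)`` or ``(chrom, start, end, score,
    summit)`` tuples, half-open 0-based.
    """

    records: list[tuple]
    source_kind: str = "annotation"
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for rec in self.records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            if not (0 <= start < end):
                raise ValueError(
                    f"malformed interval {chrom}:{start}-{end} (need 0 <= start < end)"
                )
        self._trees = {}

    def __len__(self) -> int:
        return len(self.records)

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            tree = IntervalTree()
            for rec in self.records:
                if rec[0] == chrom:
                    tree.addi(int(rec[1]), int(rec[2]), rec)
            self._trees[chrom] = tree
        return self._trees[chrom]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self._tree(chrom).overlaps(start, end)

    def sorted_records(self) -> list[tuple]:
        return sorted(self.records, key=lambda r: (r[0], int(r[1]), int(r[2])))


@dataclass(frozen=True)
class InputRegion:
    """A bin expanded symmetrically by a flank, clipped to the chromosome.

    ``region_end - region_start + pad_left + pad_right`` always equals the
    model input length ``bin_size + 2*flank``; off-chromosome padding is
    recorded so feature assembly can emit zero rows there.
    """

    bin: GenomicBin
    region_start: int
    region_end: int
    pad_left: int = 0
    pad_right: int = 0

    @property
    def length(self) -> int:
        return self.region_end - self.region_start + self.pad_left + self.pad_right


def make_bins(
    chrom_length: int,
    bin_size: int = BIN_SIZE,
    step: int = BIN_STEP,
    chrom: str = "chr",
    cell_type: str | None = None,
) -> list[GenomicBin]:
    """Tile a chromosome with sliding bins ``[k*step, k*step + bin_size)``.

    Only fully on-chromosome bins are produced; a chromosome shorter than
    ``bin_size`` yields an empty list.
    """
    if bin_size <= 0 or step <= 0:
        raise ValueError("bin_size and step must be positive")
    if step > bin_size:
        raise ValueError("step must not exceed bin_size")
    if chrom_length < bin_size:
        return []
    n = (chrom_length - bin_size) // step + 1
    return [
        GenomicBin(chrom, k * step, k * step + bin_size, cell_type=cell_type)
        for k in range(n)
    ]


def label_bins(
    bins: Sequence[GenomicBin],
    conservative_peaks: IntervalSet,
    relaxed_peaks: IntervalSet,
    min_overlap: int = 1,
) -> list[GenomicBin]:
    """Assign B/A/U labels from conservative (reproducible) and relaxed peaks.

    Precedence: any overlap (>= ``min_overlap`` bp) with a conservative peak
    gives ``B``; otherwise an overlap with a relaxed peak gives ``A``;
    otherwise ``U``.  Every bin receives exactly one label.
    """
    def hits(peaks: IntervalSet, b: GenomicBin) -> bool:
        if not peaks.overlaps(b.chrom, b.start, b.end):
            return False
        return min_overlap <= 1 or _max_overlap(peaks, b) >= min_overlap

    out = []
    for b in bins:
        if hits(conservative_peaks, b):
            lab = "B"
        elif hits(relaxed_peaks, b):
            lab = "A"
        else:
            lab = "U"
        out.append(replace(b, label=lab))
    return out


def _max_overlap(peaks: IntervalSet, b: GenomicBin) -> int:
    best = 0
    for iv in peaks._tree(b.chrom).overlap(b.start, b.end):
        best = max(best, min(iv.end, b.end) - max(iv.begin, b.start))
    return best


def expand_bin(
    b: GenomicBin, flank: int = FLANK, chrom_length: int | None = None
) -> InputRegion:
    """Expand a bin by ``flank`` bp on each side, clipping at chromosome
    bounds and recording the clipped amount as padding."""
    start = b.start - flank
    end = b.end + flank
    pad_left = max(0, -start)
    region_start = max(0, start)
    if chrom_length is not None:
        pad_right = max(0, end - chrom_length)
        region_end = min(end, chrom_length)
    else:
        pad_right = 0
        region_end = end
    return InputRegion(b, region_start, region_end, pad_left, pad_right)


def apply_blacklist(
    bins: Sequence[GenomicBin],
    blacklist: IntervalSet,
    mode: Literal["drop", "zero"] = "drop",
):
    """Remove (``drop``) or flag (``zero``) bins overlapping blacklist regions.

    ``drop`` returns the surviving bins (for training data).  ``zero``
    returns a dict mapping each overlapping bin to the forced prediction
    score 0.0 (for prediction post-processing).
    """
    if mode == "drop":
        return [b for b in bins if not blacklist.overlaps(b.chrom, b.start, b.end)]
    if mode == "zero":
        return {
            b: 0.0 for b in bins if blacklist.overlaps(b.chrom, b.start, b.end)
        }
    raise ValueError(f"unknown mode {mode!r}")


# -- standard formats --------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read BED3+ / narrowPeak (tab-separated, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    records = []
    for row in df.itertuples(index=False):
        rec = (str(row[0]), int(row[1]), int(row[2]))
        if len(row) >= 10:  # narrowPeak: signalValue col 6, summit col 9
            rec = rec + (float(row[6]), int(row[9]))
        records.append(rec)
    return IntervalSet(records)


def write_bed(intervals: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for rec in intervals:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def write_narrowpeak(records: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, score, summit) records as narrowPeak rows."""
    with open(path, "w") as fh:
        for i, (chrom, start, end, score, summit) in enumerate(records):
            fh.write(
                f"{chrom}\t{start}\t{end}\tpeak{i}\t0\t.\t{score:.4f}\t-1\t-1\t{summit}\n"
            )


def write_label_tsv(
    bins_by_cell: dict[str, Sequence[GenomicBin]], path
) -> pd.DataFrame:
    """Write the ENCODE-DREAM-style label table: one row per bin, one B/U/A
    column per cell type.  Bin coordinates must agree across cell types."""
    cells = list(bins_by_cell)
    first = bins_by_cell[cells[0]]
    data = {
        "chr": [b.chrom for b in first],
        "start": [b.start for b in first],
        "stop": [b.end for b in first],
    }
    for cell in cells:
        bins = bins_by_cell[cell]
        if len(bins) != len(first):
            raise ValueError("cell types disagree on bin tiling")
        data[cell] = [b.label for b in bins]
    df = pd.DataFrame(data)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_label_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chr", "start", "stop"}
    if not required.issubset(df.columns):
        raise ValueError(f"label TSV must have columns {sorted(required)}")
    return df


def bins_from_label_frame(df: pd.DataFrame, cell: str) -> list[GenomicBin]:
    return [
        GenomicBin(str(r.chr), int(r.start), int(r.stop), getattr(r, cell), cell)
        for r in df.itertuples(index=False)
    ]
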