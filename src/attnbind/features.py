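"""Feature encoding for model input regions.

Each input region (default 1000 bp: a 200 bp bin plus 400 bp flanks) is
encoded as an L x C *sequential feature block* per strand — C = 4 one-hot
sequence channels, one 35-mer uniqueness (mappability) channel and one
chromatin-accessibility channel, optionally extended with a conservation
channel and a binary CpG-island channel.  Alongside it, a length-14
*non-sequential vector* carries six binary genomic-annotation flags and
eight principal-component scores of the cell type's expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .intervals import GenomicBin, InputRegion, IntervalSet

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_COMPLEMENT_COLS = np.array([3, 2, 1, 0])  # A<->T, C<->G in column space

ANNOTATION_CATEGORIES = (
    "coding",
    "intron",
    "promoter",
    "utr5",
    "utr3",
    "cpg_island",
)

UNIQUENESS_K = 35  # 35 bp mappability convention
N_EXPRESSION_PCS = 8


@dataclass
class SequentialFeatureBlock:
    """The L x C per-strand input tensor.

    Channel order is fixed: A, C, G, T, uniqueness, accessibility
    [, conservation, CGI].  Padded (off-chromosome) rows are all-zero
    across every channel.
    """

    matrix: np.ndarray
    strand: Literal["forward", "reverse_complement"] = "forward"

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NonSequentialVector:
    annotation_bits: np.ndarray  # 6 binary flags
    expression_pcs: np.ndarray  # 8 reals

    def concat(self) -> np.ndarray:
        v = np.concatenate([self.annotation_bits, self.expression_pcs])
        assert v.shape == (len(ANNOTATION_CATEGORIES) + N_EXPRESSION_PCS,)
        return v


@dataclass
class CGIWindowCounts:
    n_cpg: int
    n_c: int
    n_g: int
    length: int


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode DNA (columns A,C,G,T); ``N`` rows are all-zero."""
    seq = sequence.upper()
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, ch in enumerate(seq):
        if ch == "N":
            continue
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise ValueError(f"invalid base {ch!r} at position {i}")
        out[i, j] = 1.0
    return out


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def reverse_complement_block(block: SequentialFeatureBlock) -> SequentialFeatureBlock:
    """Complement the one-hot channels and reverse all channels along L.

    Scalar tracks (uniqueness, accessibility, extras) are strand-agnostic
    and are only reversed.
    """
    m = block.matrix
    cols = np.concatenate([_COMPLEMENT_COLS, np.arange(4, m.shape[1])])
    out = m[::-1, :][:, cols].copy()
    strand = (
        "reverse_complement" if block.strand == "forward" else "forward"
    )
    return SequentialFeatureBlock(out, strand)


def uniqueness_track(
    genome: Mapping[str, str], k: int = UNIQUENESS_K
) -> dict[str, np.ndarray]:
    """Per-base k-mer uniqueness score for every chromosome.

    The score at position p reflects how often the k-mer starting at p
    occurs in the whole genome, counting both strands: 1 occurrence -> 1;
    2..4 occurrences -> 1/occurrences; more than 4 -> 0.  The trailing
    k-1 positions of each chromosome (no full k-mer) score 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for seq in genome.values():
        s = seq.upper()
        for strand_seq in (s, reverse_complement(s)):
            for p in range(len(strand_seq) - k + 1):
                kmer = strand_seq[p : p + k]
                counts[kmer] = counts.get(kmer, 0) + 1
    tracks = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        track = np.zeros(len(s), dtype=np.float64)
        for p in range(len(s) - k + 1):
            occ = counts[s[p : p + k]]
            track[p] = 0.0 if occ > 4 else 1.0 / occ
        tracks[chrom] = track
    return tracks


def normalize_coverage_1x(
    track: np.ndarray, effective_genome_size: int
) -> np.ndarray:
    """Scale a per-base coverage track so its genome-wide mean is 1 (RPGC).

    An all-zero track is returned unchanged.
    """
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be positive")
    track = np.asarray(track, dtype=np.float64)
    if np.any(track < 0):
        raise ValueError("coverage counts must be non-negative")
    total = track.sum()
    if total == 0:
        return track.copy()
    return track * (effective_genome_size / total)


def annotation_vector(
    b: GenomicBin, annotation_sets: Mapping[str, IntervalSet]
) -> np.ndarray:
    """Six binary flags: does the bin overlap each annotation category?"""
    if set(annotation_sets) != set(ANNOTATION_CATEGORIES):
        raise ValueError(
            f"expected annotation categories {ANNOTATION_CATEGORIES}, "
            f"got {tuple(annotation_sets)}"
        )
    return np.array(
        [
            1.0 if annotation_sets[name].overlaps(b.chrom, b.start, b.end) else 0.0
            for name in ANNOTATION_CATEGORIES
        ]
    )


def expression_pcs(
    tpm_matrix: pd.DataFrame,
    n_components: int = N_EXPRESSION_PCS,
    log_transform: bool = False,
) -> dict[str, np.ndarray]:
    """Map each cell type to its first ``n_components`` PCA scores.

    The TPM matrix is genes x cell-types; each cell type is one
    observation over genes.  Observations are centered (no variance
    scaling) before the decomposition; component signs are fixed by making
    each component's largest-magnitude loading positive, so results are
    deterministic across platforms.  If fewer components exist than
    requested (at most n_cell_types - 1 can), the remainder is zero.
    """
    cells = list(tpm_matrix.columns)
    if len(cells) < 2:
        raise ValueError("expression PCA needs at least two cell types")
    X = tpm_matrix.to_numpy(dtype=np.float64).T  # cell types x genes
    if np.any(X < 0):
        raise ValueError("TPM values must be non-negative")
    if log_transform:
        X = np.log1p(X)
    n_avail = min(n_components, len(cells) - 1, X.shape[1])
    pca = PCA(n_components=n_avail)
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_avail):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    full = np.zeros((len(cells), n_components))
    full[:, :n_avail] = scores
    return {cell: full[i].copy() for i, cell in enumerate(cells)}


def cgi_score(counts: CGIWindowCounts) -> int:
    """Binary CpG-island score of a window.

    1 iff the observed/expected CpG ratio N_CpG * L / ((N_C + N_G)/2)^2
    exceeds 0.6 and the GC fraction (N_C + N_G)/L exceeds 0.5.
    """
    if counts.length <= 0:
        raise ValueError("window length must be positive")
    gc = counts.n_c + counts.n_g
    if gc == 0:
        return 0
    obs_exp = counts.n_cpg * counts.length / (gc / 2.0) ** 2
    return int(obs_exp > 0.6 and gc / counts.length > 0.5)


def cgi_counts(window: str) -> CGIWindowCounts:
    w = window.upper()
    return CGIWindowCounts(
        n_cpg=sum(1 for i in range(len(w) - 1) if w[i : i + 2] == "CG"),
        n_c=w.count("C"),
        n_g=w.count("G"),
        length=len(w),
    )


def cgi_track(sequence: str, window: int = 200) -> np.ndarray:
    """Per-base binary CGI track: the score of a ``window``-bp sliding
    window centered on each base (clipped at chromosome ends)."""
    seq = sequence.upper()
    n = len(seq)
    is_c = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("C")
    is_g = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("G")
    is_cpg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    half = window // 2
    out = np.zeros(n, dtype=np.float64)
    for p in range(n):
        lo = max(0, p - half)
        hi = min(n, p + window - half)
        L = hi - lo
        gc = int(cum_c[hi] - cum_c[lo] + cum_g[hi] - cum_g[lo])
        ncpg = int(cum_cpg[min(hi - 1, n - 1)] - cum_cpg[lo]) if L > 1 else 0
        if gc == 0:
            continue
        if ncpg * L / (gc / 2.0) ** 2 > 0.6 and gc / L > 0.5:
            out[p] = 1.0
    return out


class FeatureAssembler:
    """Builds per-region feature-block pairs from whole-chromosome tracks.

    Per-chromosome channel matrices are materialised once; a region's
    block is then a cheap slice, which matters because sliding bins
    overlap heavily (200 bp windows every 50 bp).
    """

    def __init__(
        self,
        genome: Mapping[str, str],
        uniqueness: Mapping[str, np.ndarray],
        accessibility: Mapping[str, np.ndarray],
        conservation: Mapping[str, np.ndarray] | None = None,
        cgi: Mapping[str, np.ndarray] | None = None,
    ):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.chrom_lengths = {c: len(s) for c, s in self.genome.items()}
        self._channels: dict[str, np.ndarray] = {}
        for chrom, seq in self.genome.items():
            cols = [one_hot(seq)]
            for track_map, name in (
                (uniqueness, "uniqueness"),
                (accessibility, "accessibility"),
            ):
                track = np.asarray(track_map[chrom], dtype=np.float64)
                if track.shape[0] != len(seq):
                    raise ValueError(
                        f"{name} track length {track.shape[0]} != chromosome "
                        f"{chrom} length {len(seq)}"
                    )
                cols.append(track[:, None])
            for extra in (conservation, cgi):
                if extra is not None:
                    track = np.asarray(extra[chrom], dtype=np.float64)
                    if track.shape[0] != len(seq):
                        raise ValueError("extra track/genome length mismatch")
                    cols.append(track[:, None])
            self._channels[chrom] = np.concatenate(cols, axis=1)

    @property
    def n_channels(self) -> int:
        return next(iter(self._channels.values())).shape[1]

    def forward_block(self, region: InputRegion) -> SequentialFeatureBlock:
        chrom = region.bin.chrom
        core = self._channels[chrom][region.region_start : region.region_end]
        if region.pad_left or region.pad_right:
            mat = np.zeros((region.length, core.shape[1]))
            mat[region.pad_left : region.pad_left + core.shape[0]] = core
        else:
            mat = core.copy()
        return SequentialFeatureBlock(mat, "forward")

    def block_pair(
        self, region: InputRegion
    ) -> tuple[SequentialFeatureBlock, SequentialFeatureBlock]:
        fwd = self.forward_block(region)
        return fwd, reverse_complement_block(fwd)

    def region_track(self, region: InputRegion, channel: int = 5) -> np.ndarray:
        """A single channel over the region (default: accessibility),
        zero-padded like the block."""
        return self.forward_block(region).matrix[:, channel]


def assemble_block(
    region: InputRegion, assembler: FeatureAssembler
) -> tuple[SequentialFeatureBlock, SequentialFeatureBlock]:
    """Forward and reverse-complement blocks for one input region."""
    return assembler.block_pair(region)
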