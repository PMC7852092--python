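"""Attention and saliency interpretation: mapping attention weights back
to genome coordinates, extracting candidate motif windows under attention
peaks, scanning them with a PWM, and correlating attention with ChIP-Seq
fold-change signal.

The attention axis is coarser than the input (convolution plus pooling),
so every trace carries an affine coordinate map: genomic bp = origin +
position * downsample_factor, where the origin sits at the center of
attention position 0's receptive field.  Reverse-complement-strand traces
are flipped along the position axis before any cross-strand comparison,
so both strands share that map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import autodiff as ad
from .autodiff import Tensor
from .features import FeatureAssembler
from .intervals import GenomicBin, InputRegion, expand_bin
from .model import AttentionTrace, DualAttentionModel

MOTIF_WINDOW = 20  # bp extracted around each attention peak


@dataclass(frozen=True)
class MotifWindow:
    chrom: str
    start: int
    end: int
    source_bin: GenomicBin
    attention_peak_coord: int
    sequence: str = ""


def _region_origins(model: DualAttentionModel, region: InputRegion) -> tuple[int, int]:
    """Genomic bp of attention position 0 for the forward trace and for the
    position-reversed RC trace.

    Max-pooling drops trailing convolution outputs, so the RC grid is
    offset from the forward grid by L-1 - 2*offset - (l-1)*pool bp (9 bp at
    the defaults); both origins are tracked so traces can be aligned.
    """
    cfg = model.config
    block_start = region.bin.start - cfg.flank  # block row 0, may be off-chrom
    origin_fwd = block_start + cfg.attention_offset
    l = cfg.n_attention_positions
    origin_rc = block_start + (cfg.seq_length - 1) - cfg.attention_offset \
        - (l - 1) * cfg.pool_size
    return origin_fwd, origin_rc


def strand_average(
    fwd: AttentionTrace, rc: AttentionTrace
) -> tuple[np.ndarray, AttentionTrace]:
    """Average a forward trace with the (already reversed) RC trace after
    aligning their coordinate grids by the integer position shift between
    the two origins."""
    shift = int(round((rc.origin - fwd.origin) / fwd.downsample_factor))
    w = fwd.weights.copy()
    rcw = rc.weights
    n = len(w)
    for j in range(n):
        k = j - shift
        k = min(max(k, 0), n - 1)
        w[j] = 0.5 * (w[j] + rcw[k])
    return w, fwd


def extract_attention(
    model: DualAttentionModel,
    region: InputRegion,
    assembler: FeatureAssembler,
    nonseq: np.ndarray,
    return_matrices: bool = False,
) -> dict[tuple[str, str], AttentionTrace]:
    """Attention traces of both branches on both strands for one region.

    Reverse-complement traces are reversed along the position axis so
    that both strands use the forward coordinate map.
    """
    fwd, rc = assembler.block_pair(region)
    with ad.no_grad():
        _, traces = model.forward(
            fwd.matrix[None], rc.matrix[None], nonseq[None],
            return_traces=True, return_matrices=return_matrices,
        )
    origin_fwd, origin_rc = _region_origins(model, region)
    out = {}
    for (branch, strand), tr in traces.items():
        w = tr.weights[0]
        mat = tr.matrix[0] if tr.matrix is not None else None
        origin = origin_fwd
        if strand == "reverse_complement":
            w = w[::-1].copy()
            origin = origin_rc
            if mat is not None:
                mat = mat[::-1, ::-1].copy()
        out[(branch, strand)] = AttentionTrace(
            w, branch, strand, model.config.downsample_factor, origin, mat
        )
    return out


def saliency(
    model: DualAttentionModel,
    region: InputRegion,
    assembler: FeatureAssembler,
    nonseq: np.ndarray,
    reduction: str = "max_abs",
) -> dict[str, np.ndarray]:
    """Per-position saliency: gradient of the output score w.r.t. the
    sequential input, reduced over channels (max of absolute values, or
    L2).  The reverse-complement strand is reversed before returning."""
    fwd, rc = assembler.block_pair(region)
    xf = Tensor(fwd.matrix[None], requires_grad=True)
    xr = Tensor(rc.matrix[None], requires_grad=True)
    score = model.forward(xf, xr, nonseq[None])
    score.backward()
    out = {}
    for strand, x in (("forward", xf), ("reverse_complement", xr)):
        g = np.zeros_like(x.data[0]) if x.grad is None else x.grad[0]
        if reduction == "max_abs":
            s = np.abs(g).max(axis=1)
        elif reduction == "l2":
            s = np.sqrt((g * g).sum(axis=1))
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
        if strand == "reverse_complement":
            s = s[::-1].copy()
        out[strand] = s
    return out


def filter_candidate_bins(
    bins: list[GenomicBin],
    predictions: np.ndarray,
    assembler: FeatureAssembler,
    flank: int,
    score_threshold: float = 0.5,
    peak_ratio_limit: float = 15.0,
) -> list[int]:
    """Indices of predicted-positive bins without a dominant accessibility
    peak (max/mean coverage ratio below the limit within the region) —
    the bins where the sequence, not the accessibility spike, must carry
    the prediction."""
    keep = []
    for i, b in enumerate(bins):
        if predictions[i] <= score_threshold:
            continue
        region = expand_bin(b, flank, assembler.chrom_lengths[b.chrom])
        track = assembler.region_track(region)
        m = track.mean()
        if m <= 0:
            continue
        if track.max() / m < peak_ratio_limit:
            keep.append(i)
    return keep


def extract_motif_windows(
    bins: list[GenomicBin],
    model: DualAttentionModel,
    assembler: FeatureAssembler,
    nonseq: np.ndarray,
    branch: str = "pairwise",
    window: int = MOTIF_WINDOW,
) -> list[MotifWindow]:
    """A ``window``-bp subsequence centered on each bin's attention peak.

    The peak is the (leftmost) argmax of the pairwise branch's attention
    column sums (or the single branch's per-position weights), averaged
    over strands, mapped to genomic bp through the trace's coordinate
    map; windows are clipped to stay inside the input region.
    """
    out = []
    for b in bins:
        chrom_len = assembler.chrom_lengths[b.chrom]
        region = expand_bin(b, model.config.flank, chrom_len)
        traces = extract_attention(model, region, assembler, nonseq)
        w, tr = strand_average(
            traces[(branch, "forward")], traces[(branch, "reverse_complement")]
        )
        pos = int(np.argmax(w))  # argmax takes the leftmost tie
        center = tr.position_to_genomic(pos)
        start = center - window // 2
        start = max(region.region_start, min(start, region.region_end - window))
        end = start + window
        seq = assembler.genome[b.chrom][start:end]
        out.append(MotifWindow(b.chrom, start, end, b, center, seq))
    return out


def write_windows(windows: list[MotifWindow], bed_path, fasta_path) -> None:
    with open(bed_path, "w") as bed, open(fasta_path, "w") as fa:
        for i, w in enumerate(windows):
            name = f"window{i}_{w.chrom}_{w.start}"
            bed.write(f"{w.chrom}\t{w.start}\t{w.end}\t{name}\n")
            fa.write(f">{name}\n{w.sequence}\n")


# ---------------------------------------------------------------------------
# PWM scanning (internal FIMO-free motif matcher)
# ---------------------------------------------------------------------------

_BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_scan(
    sequences: list[str],
    pwm: np.ndarray,
    background: float = 0.25,
    floor: float = 1e-3,
) -> list[tuple[float, int, str]]:
    """Best log2-odds PWM match per sequence over all offsets and both
    strands.  Returns (score, offset, strand) per sequence; ties resolve
    to the leftmost offset on the forward strand.  Zero PWM entries are
    floored at ``floor`` before taking logs."""
    pwm = np.asarray(pwm, dtype=np.float64)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must be (width, 4) over A,C,G,T")
    logodds = np.log2(np.maximum(pwm, floor) / background)
    rc_logodds = logodds[::-1, ::-1]
    width = pwm.shape[0]
    results = []
    for seq in sequences:
        s = seq.upper()
        if len(s) < width:
            raise ValueError("sequence shorter than PWM width")
        cols = np.array([_BASE_TO_COL.get(ch, -1) for ch in s])
        best = (-np.inf, 0, "+")
        for mat, strand in ((logodds, "+"), (rc_logodds, "-")):
            for off in range(len(s) - width + 1):
                window = cols[off : off + width]
                if np.any(window < 0):  # N base: skip this placement
                    continue
                score = float(mat[np.arange(width), window].sum())
                if score > best[0]:
                    best = (score, off, strand)
        results.append(best)
    return results


def load_motif(path, fmt: str = "jaspar") -> np.ndarray:
    """Read a PWM from JASPAR PFM or MEME minimal format as a (width, 4)
    probability matrix over A,C,G,T."""
    from Bio import motifs

    with open(path) as fh:
        m = motifs.read(fh, fmt)
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=np.float64).T
    row_sums = counts.sum(axis=1, keepdims=True)
    return counts / np.where(row_sums == 0, 1.0, row_sums)


# ---------------------------------------------------------------------------
# attention vs ChIP-Seq fold-change
# ---------------------------------------------------------------------------

def track_per_attention_position(
    track: np.ndarray, n_positions: int, downsample: int, offset: int
) -> np.ndarray:
    """Average a per-base region track over each attention position's
    ``downsample``-bp window (centered at offset + pos*downsample)."""
    out = np.zeros(n_positions)
    for a in range(n_positions):
        center = offset + a * downsample
        lo = max(0, center - downsample // 2)
        hi = min(len(track), center + (downsample + 1) // 2)
        out[a] = track[lo:hi].mean() if hi > lo else 0.0
    return out


def attention_signal_correlation(
    attention_values: np.ndarray, signal_values: np.ndarray
) -> tuple[float, float]:
    """Pearson and Spearman correlation between pooled attention weights
    and matched fold-change values, both z-scored."""
    a = np.asarray(attention_values, dtype=np.float64)
    s = np.asarray(signal_values, dtype=np.float64)
    if a.shape != s.shape:
        raise ValueError("attention and signal vectors must align")
    if a.std() == 0 or s.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    az = (a - a.mean()) / a.std()
    sz = (s - s.mean()) / s.std()
    pearson = float(stats.pearsonr(az, sz)[0])
    spearman = float(stats.spearmanr(az, sz)[0])
    return pearson, spearman


def pooled_attention_vs_signal(
    bins: list[GenomicBin],
    model: DualAttentionModel,
    assembler: FeatureAssembler,
    nonseq: np.ndarray,
    fold_change: dict[str, np.ndarray],
    branch: str = "single",
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (attention, fold-change) pairs over bins: strand-averaged
    attention per position against the fold-change track averaged over the
    matching windows."""
    cfg = model.config
    att_all, sig_all = [], []
    for b in bins:
        region = expand_bin(b, cfg.flank, assembler.chrom_lengths[b.chrom])
        traces = extract_attention(model, region, assembler, nonseq)
        w, _ = strand_average(
            traces[(branch, "forward")], traces[(branch, "reverse_complement")]
        )
        block_start = b.start - cfg.flank
        fc = fold_change[b.chrom]
        lo = max(0, block_start)
        track = np.zeros(cfg.seq_length)
        seg = fc[lo : block_start + cfg.seq_length]
        track[lo - block_start : lo - block_start + len(seg)] = seg
        sig = track_per_attention_position(
            track, len(w), cfg.downsample_factor, cfg.attention_offset
        )
        att_all.append(w)
        sig_all.append(sig)
    return np.concatenate(att_all), np.concatenate(sig_all)


def permutation_pvalue(
    attention_values: np.ndarray,
    signal_values: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation test for a positive Pearson correlation.

    Returns (observed r, p-value under random pairings).
    """
    rng = np.random.default_rng(seed)
    r_obs, _ = attention_signal_correlation(attention_values, signal_values)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(attention_values))
        r, _ = attention_signal_correlation(attention_values[perm], signal_values)
        if r >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_permutations + 1)
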