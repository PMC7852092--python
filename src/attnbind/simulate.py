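"""Seeded desk-scale synthetic fixtures: a random genome with planted
motif instances, accessibility and ChIP fold-change tracks, peak calls,
and the three-way (B/U/A) label table, emitted in the standard formats
the rest of the pipeline consumes.

The generator encodes the statistical structure the method exploits:
binding requires *both* a motif instance and open chromatin.  True bound
sites carry a planted PWM motif plus an accessibility peak; decoys
violate exactly one of the two (accessible but motif-free, or motif-
bearing but closed).  Cell types share the genome and the motif but
differ in which bound sites are accessible — the cross-cell-type signal a
binding predictor must generalise over.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .intervals import (
    GenomicBin,
    IntervalSet,
    label_bins,
    make_bins,
    write_bed,
    write_label_tsv,
    write_narrowpeak,
)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults give a 200 kb genome split over two chromosomes with 20 true
    bound sites, 20 accessible-but-motif-free decoys and 20 closed motif
    decoys; accessibility peaks are Gaussian bumps (height 10, sd 40 bp)
    on a baseline of 1 with mild noise, ChIP fold-change bumps are height
    10, sd 75 bp on baseline 1.
    """

    genome_length: int = 200_000
    n_chroms: int = 3
    gc_content: float = 0.5
    motif_consensus: str = "TGACGTCATC"
    motif_sharpness: float = 0.95
    n_bound_sites: int = 20
    n_decoy_accessible: int = 20
    n_decoy_motif: int = 20
    access_sd: float = 40.0
    access_height: float = 10.0
    access_baseline: float = 1.0
    access_noise: float = 0.05
    fc_sd: float = 75.0
    fc_height: float = 10.0
    fc_baseline: float = 1.0
    peak_halfwidth: int = 100
    ambiguous_fraction: float = 0.25
    accessible_fraction: float = 0.75
    label_noise: float = 0.0
    n_cell_types: int = 2
    n_genes: int = 50
    n_blacklist: int = 2
    blacklist_width: int = 500
    site_margin: int = 1000
    min_separation: int = 1500
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    genome: dict[str, str]
    bound_sites: list[tuple[str, int]]  # (chrom, start) of motif instances
    decoy_accessible: list[tuple[str, int]]
    decoy_motif: list[tuple[str, int]]
    accessible: dict[str, np.ndarray]  # cell -> bool per bound site
    accessibility: dict[str, dict[str, np.ndarray]]  # cell -> chrom -> track
    fold_change: dict[str, dict[str, np.ndarray]]
    conservative_peaks: dict[str, IntervalSet]
    relaxed_peaks: dict[str, IntervalSet]
    labels: dict[str, list[GenomicBin]]  # cell -> labeled bins
    label_frame: pd.DataFrame
    expression: pd.DataFrame
    blacklist: IntervalSet
    annotations: dict[str, IntervalSet]
    manifest: dict = field(default_factory=dict)

    @property
    def motif_width(self) -> int:
        return len(self.config.motif_consensus)

    def bound_site_set(self, cell: str | None = None) -> IntervalSet:
        """Planted motif spans of bound sites (optionally only the ones
        accessible, hence bound, in ``cell``)."""
        w = self.motif_width
        if cell is None:
            recs = [(c, p, p + w) for c, p in self.bound_sites]
        else:
            mask = self.accessible[cell]
            recs = [
                (c, p, p + w)
                for (c, p), acc in zip(self.bound_sites, mask)
                if acc
            ]
        return IntervalSet(recs, source_kind="annotation")

    def cell_names(self) -> list[str]:
        return list(self.accessible)


def make_pwm(consensus: str, sharpness: float = 0.95) -> np.ndarray:
    """PWM with the consensus base at probability sharpness + (1-s)/4 and
    the rest uniform; sharpness 1 is a deterministic consensus."""
    if not consensus:
        raise ValueError("empty consensus")
    if not 0 < sharpness <= 1:
        raise ValueError("sharpness must be in (0, 1]")
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((len(consensus), 4), (1.0 - sharpness) / 4.0)
    for i, ch in enumerate(consensus.upper()):
        if ch not in base_idx:
            raise ValueError(f"invalid consensus base {ch!r}")
        pwm[i, base_idx[ch]] += sharpness
    return pwm


def _sample_motif(pwm: np.ndarray, rng: np.random.Generator) -> str:
    bases = "ACGT"
    return "".join(bases[rng.choice(4, p=row)] for row in pwm)


def _place_sites(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    counts: dict[str, int],
    margin: int,
    min_sep: int,
) -> dict[str, list[tuple[str, int]]]:
    """Place all site kinds, non-overlapping with minimum separation."""
    placed: dict[str, list[tuple[str, int]]] = {k: [] for k in counts}
    occupied: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    chroms = list(chrom_lengths)
    order = [(kind, i) for kind in counts for i in range(counts[kind])]
    for j, (kind, _) in enumerate(order):
        chrom = chroms[j % len(chroms)]
        lo, hi = margin, chrom_lengths[chrom] - margin
        if hi <= lo:
            raise SimulationError("chromosome too short for site margins")
        for _ in range(1000):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - q) >= min_sep for q in occupied[chrom]):
                occupied[chrom].append(pos)
                placed[kind].append((chrom, pos))
                break
        else:
            raise SimulationError("could not place sites without overlap")
    return placed


def _gaussian_bump(track: np.ndarray, center: int, height: float, sd: float) -> None:
    lo = max(0, int(center - 4 * sd))
    hi = min(len(track), int(center + 4 * sd) + 1)
    x = np.arange(lo, hi)
    track[lo:hi] += height * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate(config: SimulationConfig, outdir: str | Path | None = None) -> SyntheticTruth:
    """Generate the full fixture; write standard-format files when
    ``outdir`` is given.  Byte-identical across runs for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    per = cfg.genome_length // cfg.n_chroms
    chrom_names = [f"chr{chr(ord('A') + i)}" for i in range(cfg.n_chroms)]
    chrom_lengths = {c: per for c in chrom_names}
    pwm = make_pwm(cfg.motif_consensus, cfg.motif_sharpness)
    w = len(cfg.motif_consensus)

    sites = _place_sites(
        rng, chrom_lengths,
        {"bound": cfg.n_bound_sites,
         "decoy_accessible": cfg.n_decoy_accessible,
         "decoy_motif": cfg.n_decoy_motif,
         "blacklist": cfg.n_blacklist},
        cfg.site_margin, cfg.min_separation,
    )

    # genome with planted motifs at bound and closed-decoy sites
    p = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                  cfg.gc_content / 2, (1 - cfg.gc_content) / 2])
    genome = {}
    for chrom in chrom_names:
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                         size=chrom_lengths[chrom], p=p)
        genome[chrom] = arr.tobytes().decode()
    for chrom, pos in sites["bound"] + sites["decoy_motif"]:
        inst = _sample_motif(pwm, rng)
        s = genome[chrom]
        genome[chrom] = s[:pos] + inst + s[pos + w:]

    cells = [f"cell{chr(ord('A') + i)}" for i in range(cfg.n_cell_types)]
    accessible: dict[str, np.ndarray] = {}
    for cell in cells:
        for _ in range(1000):
            mask = rng.random(cfg.n_bound_sites) < cfg.accessible_fraction
            per_chrom = {c: 0 for c in chrom_names}
            for (chrom, _), acc in zip(sites["bound"], mask):
                per_chrom[chrom] += int(acc)
            if all(v >= 1 for v in per_chrom.values()):
                break
        else:
            raise SimulationError("could not draw accessible subsets")
        accessible[cell] = mask

    accessibility: dict[str, dict[str, np.ndarray]] = {}
    fold_change: dict[str, dict[str, np.ndarray]] = {}
    conservative: dict[str, IntervalSet] = {}
    relaxed: dict[str, IntervalSet] = {}
    half = cfg.peak_halfwidth
    for cell in cells:
        acc_tracks = {
            c: np.full(chrom_lengths[c], cfg.access_baseline) for c in chrom_names
        }
        fc_tracks = {
            c: np.full(chrom_lengths[c], cfg.fc_baseline) for c in chrom_names
        }
        open_sites = [
            (chrom, pos)
            for (chrom, pos), acc in zip(sites["bound"], accessible[cell])
            if acc
        ]
        for chrom, pos in open_sites + sites["decoy_accessible"]:
            _gaussian_bump(acc_tracks[chrom], pos + w // 2,
                           cfg.access_height, cfg.access_sd)
        for chrom, pos in open_sites:
            _gaussian_bump(fc_tracks[chrom], pos + w // 2,
                           cfg.fc_height, cfg.fc_sd)
        if cfg.access_noise > 0:
            for c in chrom_names:
                acc_tracks[c] = np.maximum(
                    0.0,
                    acc_tracks[c]
                    + rng.normal(0, cfg.access_noise, chrom_lengths[c]),
                )
        cons_recs = [
            (chrom, max(0, pos + w // 2 - half), pos + w // 2 + half,
             cfg.fc_height, half)
            for chrom, pos in open_sites
        ]
        n_ambig = int(round(cfg.ambiguous_fraction * len(sites["decoy_accessible"])))
        ambig_idx = rng.choice(
            len(sites["decoy_accessible"]), size=n_ambig, replace=False
        ) if n_ambig else np.array([], dtype=int)
        ambig_recs = [
            (sites["decoy_accessible"][i][0],
             max(0, sites["decoy_accessible"][i][1] + w // 2 - half),
             sites["decoy_accessible"][i][1] + w // 2 + half,
             cfg.fc_height / 4, half)
            for i in sorted(ambig_idx)
        ]
        accessibility[cell] = acc_tracks
        fold_change[cell] = fc_tracks
        conservative[cell] = IntervalSet(cons_recs, "conservative_peaks")
        relaxed[cell] = IntervalSet(cons_recs + ambig_recs, "relaxed_peaks")

    # labels per cell (shared bin tiling)
    labels: dict[str, list[GenomicBin]] = {}
    for cell in cells:
        bins = []
        for chrom in chrom_names:
            bins.extend(make_bins(chrom_lengths[chrom], chrom=chrom, cell_type=cell))
        labeled = label_bins(bins, conservative[cell], relaxed[cell])
        if cfg.label_noise > 0:
            flip = rng.random(len(labeled)) < cfg.label_noise
            labeled = [
                dataclasses.replace(b, label=("U" if b.label == "B" else "B"))
                if f and b.label in "BU" else b
                for b, f in zip(labeled, flip)
            ]
        labels[cell] = labeled

    # expression matrix with cell-type structure
    base = rng.lognormal(mean=2.0, sigma=1.0, size=cfg.n_genes)
    expr = {
        cell: base * rng.lognormal(0.0, 0.5, cfg.n_genes) for cell in cells
    }
    expression = pd.DataFrame(
        expr, index=[f"gene{i}" for i in range(cfg.n_genes)]
    ).round(4)

    blacklist = IntervalSet(
        [(c, pos, pos + cfg.blacklist_width) for c, pos in sites["blacklist"]],
        "blacklist",
    )

    ann_rng = np.random.default_rng([cfg.seed, 7])
    annotations = {}
    from .features import ANNOTATION_CATEGORIES

    for name in ANNOTATION_CATEGORIES:
        recs = []
        for _ in range(30):
            chrom = chrom_names[int(ann_rng.integers(0, cfg.n_chroms))]
            width = int(ann_rng.integers(500, 2000))
            start = int(ann_rng.integers(0, chrom_lengths[chrom] - width))
            recs.append((chrom, start, start + width))
        annotations[name] = IntervalSet(recs, "annotation")

    truth = SyntheticTruth(
        config=cfg, genome=genome,
        bound_sites=sites["bound"],
        decoy_accessible=sites["decoy_accessible"],
        decoy_motif=sites["decoy_motif"],
        accessible=accessible,
        accessibility=accessibility, fold_change=fold_change,
        conservative_peaks=conservative, relaxed_peaks=relaxed,
        labels=labels, label_frame=pd.DataFrame(), expression=expression,
        blacklist=blacklist, annotations=annotations,
    )

    if outdir is not None:
        truth.manifest = _write_files(truth, Path(outdir))
    # label frame mirrors the written TSV even when nothing is written
    cells_bins = {cell: labels[cell] for cell in cells}
    first = cells_bins[cells[0]]
    frame = pd.DataFrame(
        {"chr": [b.chrom for b in first],
         "start": [b.start for b in first],
         "stop": [b.end for b in first],
         **{cell: [b.label for b in cells_bins[cell]] for cell in cells}}
    )
    truth.label_frame = frame
    return truth


def _write_files(truth: SyntheticTruth, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    paths: dict[str, str] = {}

    def reg(key: str, path: Path) -> Path:
        paths[key] = str(path)
        return path

    aio.write_fasta(truth.genome, reg("genome", outdir / "genome.fa"))
    for cell in truth.cell_names():
        write_narrowpeak(truth.conservative_peaks[cell].sorted_records(),
                         reg(f"{cell}.conservative",
                             outdir / f"{cell}.conservative.narrowPeak"))
        write_narrowpeak(truth.relaxed_peaks[cell].sorted_records(),
                         reg(f"{cell}.relaxed",
                             outdir / f"{cell}.relaxed.narrowPeak"))
        aio.write_bedgraph(truth.accessibility[cell],
                           reg(f"{cell}.dnase", outdir / f"{cell}.dnase.bedGraph"))
        aio.write_bedgraph(truth.fold_change[cell],
                           reg(f"{cell}.chip_fc", outdir / f"{cell}.chip_fc.bedGraph"))
    write_label_tsv({c: truth.labels[c] for c in truth.cell_names()},
                    reg("labels", outdir / "labels.tsv"))
    truth.expression.to_csv(reg("expression", outdir / "expression.tsv"), sep="\t")
    write_bed(truth.blacklist.sorted_records(),
              reg("blacklist", outdir / "blacklist.bed"))
    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    for name, ivs in truth.annotations.items():
        write_bed(ivs.sorted_records(), reg(f"annotation.{name}",
                                            ann_dir / f"{name}.bed"))
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "files": paths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
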