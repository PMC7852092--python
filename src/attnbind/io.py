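"""Readers/writers for FASTA and bedGraph tracks.

BED/narrowPeak and the label TSV live in :mod:`attnbind.intervals`;
motif formats in :mod:`attnbind.interpretation`.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bedgraph(tracks: Mapping[str, np.ndarray], path, decimals: int = 4) -> None:
    """Write per-base tracks as run-length-merged bedGraph intervals."""
    with open(path, "w") as fh:
        for chrom in tracks:
            vals = np.round(np.asarray(tracks[chrom], dtype=np.float64), decimals)
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.{decimals}f}\n")


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    tracks = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    for row in df.itertuples(index=False):
        if row.chrom in tracks:
            tracks[row.chrom][int(row.start): int(row.end)] = float(row.value)
    return tracks
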