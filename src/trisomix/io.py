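"""Readers and writers for the plain-text formats the pipeline exchanges.

Bin tables and gene tables are TSV; contact matrices are sparse triplet
TSV (optionally gzipped, by file extension); per-bin tracks are bedGraph.
Every reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .layout import BinTrack, GenomeLayout, validate_gene_table
from .matrix import ContactMatrix

__all__ = [
    "write_bin_table",
    "read_bin_table",
    "write_contacts",
    "read_contacts",
    "write_bedgraph",
    "read_bedgraph",
    "write_gene_table",
    "read_gene_table",
]


def write_bin_table(layout: GenomeLayout, path) -> None:
    layout.bin_table.to_csv(path, sep="\t", index=False)


def read_bin_table(path) -> GenomeLayout:
    """Reconstruct a :class:`GenomeLayout` from a chrom/start/end/index TSV."""
    tab = pd.read_csv(path, sep="\t")
    chroms = list(dict.fromkeys(tab["chrom"]))
    lengths = tab.groupby("chrom", sort=False)["end"].max()
    starts = tab["start"].to_numpy()
    bin_size = int((tab["end"] - tab["start"]).max()) if len(tab) else 1
    if len(starts) > 1:
        nz = np.diff(starts)
        nz = nz[nz > 0]
        if nz.size:
            bin_size = int(nz.min())
    return GenomeLayout(
        chrom_names=tuple(chroms),
        chrom_lengths=tuple(int(lengths[c]) for c in chroms),
        bin_size=bin_size,
    )


def write_contacts(matrix: ContactMatrix, triplet_path, bin_table_path=None) -> None:
    """Write a contact matrix as upper-triangle triplets (bin1, bin2, count)."""
    matrix.triplets().to_csv(triplet_path, sep="\t", index=False)
    if bin_table_path is not None:
        write_bin_table(matrix.layout, bin_table_path)


def read_contacts(bin_table_path, triplet_path) -> ContactMatrix:
    """Read a contact matrix from a bin table plus a triplet file.

    Triplets may reference either triangle; both are folded into the
    upper triangle.  An empty triplet file yields a valid all-zero
    matrix.
    """
    layout = read_bin_table(bin_table_path)
    trip = pd.read_csv(triplet_path, sep="\t")
    if len(trip) == 0:
        return ContactMatrix.from_triplets(layout, [], [], [])
    return ContactMatrix.from_triplets(
        layout, trip["bin1"], trip["bin2"], trip["count"]
    )


def write_bedgraph(track: BinTrack, path) -> None:
    """Write defined bins of a track as bedGraph (0-based half-open)."""
    tab = track.layout.bin_table.copy()
    tab["value"] = track.values
    tab = tab[~np.isnan(tab["value"])]
    tab[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedgraph(path, layout: GenomeLayout, name: str = "track") -> BinTrack:
    """Read a bedGraph into a track on ``layout``; uncovered bins are NaN."""
    values = np.full(layout.n_bins, np.nan)
    tab = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for chrom, sub in tab.groupby("chrom", sort=False):
        sl = layout.chrom_slice(chrom)
        idx = sl.start + sub["start"].to_numpy() // layout.bin_size
        values[idx] = sub["value"].to_numpy()
    return BinTrack(layout, values, name=name)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    validate_gene_table(genes).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    return validate_gene_table(pd.read_csv(path, sep="\t"))
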