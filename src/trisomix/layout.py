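"""Genome layouts, bin bookkeeping and per-bin tracks.

A :class:`GenomeLayout` fixes the coordinate backbone shared by every
stage of the pipeline: an ordered set of chromosomes, a bin size, and a
global 0-based bin indexing (chromosome order, then start).  Coordinates
are 0-based half-open throughout, matching dominant Hi-C tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "BinTrack",
    "build_layout",
    "gene_density_track",
    "chromosome_gene_density",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths, bin size and global bin indexing.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Length in bp of each chromosome, same order as ``chrom_names``.
    bin_size
        Bin width in bp.  The last bin of a chromosome may be short.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    bin_table: pd.DataFrame = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome name")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_table is None:
            object.__setattr__(self, "bin_table", self._make_bin_table())

    def _make_bin_table(self) -> pd.DataFrame:
        rows = []
        idx = 0
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            for start in range(0, length, self.bin_size):
                rows.append((name, start, min(start + self.bin_size, length), idx))
                idx += 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])

    # -- derived views -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bin_table)

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def chrom_offsets(self) -> dict[str, int]:
        """Global index of the first bin of each chromosome."""
        out, idx = {}, 0
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            out[name] = idx
            idx += -(-length // self.bin_size)
        return out

    def chrom_slice(self, name: str) -> slice:
        """Slice of global bin indices covering one chromosome."""
        off = self.chrom_offsets()
        if name not in off:
            raise KeyError(f"unknown chromosome {name!r}")
        n = -(-self.chrom_lengths[self.chrom_names.index(name)] // self.bin_size)
        return slice(off[name], off[name] + n)

    def bin_chrom_codes(self) -> np.ndarray:
        """Integer chromosome code (position in chrom_names) per global bin."""
        codes = np.empty(self.n_bins, dtype=np.int32)
        for ci, name in enumerate(self.chrom_names):
            codes[self.chrom_slice(name)] = ci
        return codes

    def bin_starts(self) -> np.ndarray:
        return self.bin_table["start"].to_numpy()

    def locate(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos`` on ``chrom``."""
        sl = self.chrom_slice(chrom)
        i = sl.start + pos // self.bin_size
        if i >= sl.stop:
            raise ValueError(f"position {pos} beyond end of {chrom}")
        return i


def build_layout(chrom_sizes: dict[str, int], bin_size: int) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a name -> bp mapping.

    Each chromosome gets ``ceil(length / bin_size)`` bins; the last bin of
    a chromosome is shortened to end at the chromosome length.
    """
    return GenomeLayout(
        chrom_names=tuple(chrom_sizes),
        chrom_lengths=tuple(chrom_sizes.values()),
        bin_size=int(bin_size),
    )


@dataclass
class BinTrack:
    """One numeric value per global bin; missing values are NaN, never 0.

    ``values`` has exactly ``layout.n_bins`` entries; masked/undefined
    bins are ``np.nan``.
    """

    layout: GenomeLayout
    values: np.ndarray
    name: str = "track"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} does not match "
                f"{self.layout.n_bins} bins"
            )

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def for_chrom(self, name: str) -> np.ndarray:
        return self.values[self.layout.chrom_slice(name)]


# -- gene tables -------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "exon_length_bp"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and basic sanity of a gene table."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (genes["exon_length_bp"] <= 0).any():
        raise ValueError("exon_length_bp must be positive")
    return genes


def gene_density_track(genes: pd.DataFrame, layout: GenomeLayout) -> BinTrack:
    """Per-bin gene density in genes/Mb, assigning genes by start coordinate.

    Genes on chromosomes absent from the layout are skipped with a warning.
    """
    validate_gene_table(genes)
    counts = np.zeros(layout.n_bins)
    skipped = 0
    offsets = layout.chrom_offsets()
    for chrom, sub in genes.groupby("chrom", sort=False):
        if chrom not in offsets:
            skipped += len(sub)
            continue
        sl = layout.chrom_slice(chrom)
        idx = sl.start + sub["start"].to_numpy() // layout.bin_size
        idx = idx[idx < sl.stop]
        np.add.at(counts, idx, 1.0)
    if skipped:
        warnings.warn(f"skipped {skipped} genes on chromosomes not in layout")
    widths = (layout.bin_table["end"] - layout.bin_table["start"]).to_numpy()
    density = counts / (widths / 1e6)
    return BinTrack(layout, density, name="gene_density")


def chromosome_gene_density(genes: pd.DataFrame, layout: GenomeLayout) -> pd.Series:
    """Genes per Mb for each chromosome (gene number / chromosome Mb)."""
    validate_gene_table(genes)
    n = genes[genes["chrom"].isin(layout.chrom_names)].groupby("chrom").size()
    out = {}
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        out[name] = float(n.get(name, 0)) / (length / 1e6)
    return pd.Series(out, name="genes_per_mb")
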