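"""A/B compartment calling and compartment-level statistics.

Compartments are read off the first principal component of the Pearson
correlation matrix of the per-chromosome observed/expected (O/E) contact
matrix, computed on balanced matrices (500-kb bins by convention).  The
eigenvector sign is anchored by gene density: the sign whose bins have
the higher mean gene density is A, the other B.  Two comparative
statistics follow: the fraction of bins whose A/B label switches between
two samples, and the per-chromosome segregation score — the ratio of
long-range A-B contacts to same-type (A-A plus B-B) contacts, with
short-range contacts (< 2 Mb by default) removed because they mostly
reflect within-TAD structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .layout import BinTrack, GenomeLayout
from .matrix import ContactMatrix

__all__ = [
    "CompartmentTrack",
    "SegregationResult",
    "oe_transform",
    "call_compartments",
    "switch_fraction",
    "segregation_score",
]

logger = logging.getLogger(__name__)

MIN_USABLE_BINS = 10


@dataclass
class CompartmentTrack:
    """Per-bin PC1 value and A/B label ('A', 'B' or 'masked')."""

    layout: GenomeLayout
    pc1: np.ndarray
    labels: np.ndarray  # dtype '<U6'
    low_confidence: dict[str, bool] | None = None

    @property
    def defined(self) -> np.ndarray:
        return self.labels != "masked"

    def as_track(self) -> BinTrack:
        return BinTrack(self.layout, self.pc1, name="pc1")


def oe_transform(cis: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Observed/expected transform of one chromosome's cis matrix.

    Each entry is divided by the mean of its bin-distance diagonal,
    computed over unmasked bins; diagonals with zero mean, and masked
    rows/columns, become NaN.
    """
    n = cis.shape[0]
    if mask is None:
        mask = np.ones(n, bool)
    oe = np.full((n, n), np.nan)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = mask[i] & mask[j]
        if not ok.any():
            continue
        vals = cis[i[ok], j[ok]]
        mean = vals.mean()
        if mean > 0:
            oe[i[ok], j[ok]] = cis[i[ok], j[ok]] / mean
            oe[j[ok], i[ok]] = oe[i[ok], j[ok]]
    return oe


def _chrom_pc(oe: np.ndarray, mask: np.ndarray):
    """Leading two eigenvectors of the O/E Pearson correlation matrix."""
    sub = oe[np.ix_(mask, mask)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(sub)
    if not np.isfinite(corr).all():
        return None
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return vecs[:, 0], vecs[:, 1], vals[0]


def call_compartments(
    matrix: ContactMatrix,
    density: BinTrack,
    conf_alpha: float = 0.01,
) -> CompartmentTrack:
    """Call A/B compartments per chromosome from a balanced matrix.

    For each chromosome the O/E Pearson correlation matrix is
    eigendecomposed; of the two leading components the one more
    correlated (in absolute value) with gene density is used (PC2 wins
    only rarely, and is logged).  Sign is oriented so positive bins have
    the higher mean gene density; positive -> A, negative -> B.
    Chromosomes with fewer than 10 usable bins, or a degenerate
    correlation matrix, are masked.  Because A/B identity is anchored by
    gene density, a chromosome whose chosen component does not correlate
    significantly with density (two-sided p > ``conf_alpha``) cannot be
    confidently oriented and is flagged low-confidence — the situation a
    compartment-free (noise-only) matrix produces.
    """
    if not matrix.balanced:
        warnings.warn("compartment calling expects a balanced (ICE) matrix")
    lay = matrix.layout
    pc1 = np.full(lay.n_bins, np.nan)
    labels = np.full(lay.n_bins, "masked", dtype="<U6")
    low_conf: dict[str, bool] = {}
    dense = matrix.dense()
    for chrom in lay.chrom_names:
        sl = lay.chrom_slice(chrom)
        cis = dense[sl, sl]
        marg = cis.sum(axis=1)
        mask = marg > 0
        if matrix.weights is not None:
            mask &= ~np.isnan(matrix.weights[sl])
        if mask.sum() < MIN_USABLE_BINS:
            logger.warning("chromosome %s: <%d usable bins, masked", chrom, MIN_USABLE_BINS)
            continue
        oe = oe_transform(cis, mask)
        oe_f = np.where(np.isnan(oe), 1.0, oe)
        res = _chrom_pc(oe_f, mask)
        if res is None:
            logger.warning("chromosome %s: degenerate correlation matrix, masked", chrom)
            continue
        v1, v2, _lead_eig = res
        dens = density.for_chrom(chrom)[mask]
        dens = np.where(np.isnan(dens), np.nanmean(dens), dens)
        c1 = np.corrcoef(v1, dens)[0, 1] if np.std(dens) > 0 else 0.0
        c2 = np.corrcoef(v2, dens)[0, 1] if np.std(dens) > 0 else 0.0
        if abs(c2) > abs(c1):
            logger.info("chromosome %s: PC2 chosen over PC1 (|r| %.2f vs %.2f)", chrom, abs(c2), abs(c1))
            vec, cd = v2, c2
        else:
            vec, cd = v1, c1
        # orient: positive side must have higher mean density
        pos_d = dens[vec > 0].mean() if (vec > 0).any() else -np.inf
        neg_d = dens[vec < 0].mean() if (vec < 0).any() else -np.inf
        if neg_d > pos_d:
            vec = -vec
        idx = np.flatnonzero(mask) + sl.start
        pc1[idx] = vec
        labels[idx] = np.where(vec > 0, "A", "B")
        if np.std(dens) > 0 and len(dens) > 3:
            # factor 2: the component was selected as the better of two
            p_dens = 2 * scipy.stats.pearsonr(vec, dens).pvalue
            low_conf[chrom] = bool(p_dens > conf_alpha)
        else:
            low_conf[chrom] = True
    return CompartmentTrack(lay, pc1, labels, low_confidence=low_conf)


def switch_fraction(a: CompartmentTrack, b: CompartmentTrack) -> float:
    """Fraction of jointly labeled bins whose A/B status differs."""
    if a.layout != b.layout:
        raise ValueError("tracks must share a layout")
    joint = a.defined & b.defined
    if not joint.any():
        raise ValueError("no jointly labeled bins")
    return float((a.labels[joint] != b.labels[joint]).mean())


@dataclass
class SegregationResult:
    """Per-chromosome AA/BB/AB long-range contact sums and AB/(AA+BB) score."""

    table: pd.DataFrame  # chrom, aa, bb, ab, score (NaN when undefined)

    def score(self, chrom: str) -> float:
        return float(self.table.set_index("chrom").loc[chrom, "score"])


def segregation_score(
    matrix: ContactMatrix,
    track: CompartmentTrack,
    min_dist: int = 2_000_000,
) -> SegregationResult:
    """Compartment segregation score per chromosome.

    Sums cis contacts over bin pairs at genomic distance >= ``min_dist``
    (|start_i - start_j|), partitioned by the label pair, and reports
    score = AB / (AA + BB).  Chromosomes where AA + BB = 0 (e.g. a single
    label) get a NaN score.  The score is a ratio and hence invariant to
    global depth scaling.
    """
    lay = matrix.layout
    rows = []
    dense = matrix.dense()
    starts = lay.bin_starts()
    for chrom in lay.chrom_names:
        sl = lay.chrom_slice(chrom)
        block = dense[sl, sl]
        lab = track.labels[sl]
        st = starts[sl]
        n = block.shape[0]
        i, j = np.triu_indices(n, k=1)
        keep = np.abs(st[i] - st[j]) >= min_dist
        i, j = i[keep], j[keep]
        li, lj = lab[i], lab[j]
        ok = (li != "masked") & (lj != "masked")
        i, j, li, lj = i[ok], j[ok], li[ok], lj[ok]
        counts = block[i, j]
        aa = counts[(li == "A") & (lj == "A")].sum()
        bb = counts[(li == "B") & (lj == "B")].sum()
        ab = counts[li != lj].sum()
        score = ab / (aa + bb) if (aa + bb) > 0 else np.nan
        rows.append((chrom, aa, bb, ab, score))
    return SegregationResult(
        pd.DataFrame(rows, columns=["chrom", "aa", "bb", "ab", "score"])
    )
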