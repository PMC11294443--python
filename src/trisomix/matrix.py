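"""Genome-wide contact matrices: storage, normalization and marginal statistics.

Counts are stored as a sparse upper-triangle matrix bound to a
:class:`~trisomix.layout.GenomeLayout` and queried symmetrically.  Raw
matrices feed the inter-chromosomal statistics; iteratively corrected
(ICE-balanced) matrices feed compartment and TAD calling, mirroring the
standard division of labour in Hi-C analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .layout import BinTrack, GenomeLayout

__all__ = [
    "ContactMatrix",
    "CNVResult",
    "depth_normalize",
    "ice_normalize",
    "marginals",
    "infer_cnv",
    "decay_curve",
    "matrix_correlation",
]


@dataclass
class ContactMatrix:
    """Sparse symmetric contact matrix stored as its upper triangle.

    ``weights`` holds per-bin balancing factors after ICE; masked bins
    have NaN weight and are excluded from downstream statistics.
    """

    layout: GenomeLayout
    upper: sp.csr_matrix
    balanced: bool = False
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.layout.n_bins
        if self.upper.shape != (n, n):
            raise ValueError("matrix shape does not match layout bin count")
        if (self.upper.data < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_dense(cls, layout: GenomeLayout, dense: np.ndarray, **kw) -> "ContactMatrix":
        """Build from a full symmetric dense array (upper triangle kept)."""
        return cls(layout, sp.csr_matrix(np.triu(dense)), **kw)

    @classmethod
    def from_triplets(
        cls, layout: GenomeLayout, i, j, counts, **kw
    ) -> "ContactMatrix":
        """Build from bin-pair triplets; either triangle accepted.

        Both orientations are folded into the upper triangle by summation;
        duplicated pairs warn.
        """
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts, dtype=float)
        n = layout.n_bins
        bad = (i < 0) | (i >= n) | (j < 0) | (j >= n)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"triplet row {row}: bin index ({i[row]},{j[row]}) out of range 0..{n - 1}"
            )
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        if len(counts):
            n_unique = np.unique(np.stack([lo, hi]), axis=1).shape[1]
            if n_unique < len(counts):
                warnings.warn("duplicate bin pairs in triplets were summed")
        coo = sp.coo_matrix((counts, (lo, hi)), shape=(n, n))
        csr = coo.tocsr()
        csr.sum_duplicates()
        return cls(layout, csr, **kw)

    # -- views ---------------------------------------------------------
    def dense(self) -> np.ndarray:
        """Full symmetric dense array (diagonal counted once)."""
        u = self.upper.toarray()
        return u + np.triu(u, 1).T

    def sym(self) -> sp.csr_matrix:
        """Full symmetric sparse matrix."""
        u = self.upper
        return (u + sp.triu(u, 1).T).tocsr()

    @property
    def total(self) -> float:
        """Sum over the full symmetric matrix (off-diagonals counted twice)."""
        u = self.upper
        return float(u.sum() + sp.triu(u, 1).sum())

    def cis_dense(self, chrom: str) -> np.ndarray:
        sl = self.layout.chrom_slice(chrom)
        return self.dense()[sl, sl]

    def scaled(self, factor: float) -> "ContactMatrix":
        return replace(self, upper=self.upper * factor)

    def triplets(self) -> pd.DataFrame:
        coo = self.upper.tocoo()
        return pd.DataFrame(
            {"bin1": coo.row, "bin2": coo.col, "count": coo.data}
        ).sort_values(["bin1", "bin2"], ignore_index=True)


# -- normalization -----------------------------------------------------


def depth_normalize(a: ContactMatrix, target_total: float) -> ContactMatrix:
    """Scale all entries so the symmetric-matrix total equals ``target_total``."""
    if a.total <= 0:
        raise ValueError("cannot depth-normalize an all-zero matrix")
    return a.scaled(target_total / a.total)


def marginals(a: ContactMatrix) -> BinTrack:
    """Per-bin sum over the full symmetric matrix, diagonal counted once."""
    m = np.asarray(a.sym().sum(axis=1)).ravel()
    return BinTrack(a.layout, m, name="marginal")


def ice_normalize(
    a: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    low_cov_quantile: float = 0.02,
    scope: str = "genome",
) -> ContactMatrix:
    """Iterative correction: equalize bin marginals (ICE balancing).

    Bins whose coverage is below the ``low_cov_quantile`` quantile of
    nonzero marginals (plus zero-coverage bins) are masked before
    balancing.  Iterates ``w_i <- w_i / (marginal_i / mean marginal)``
    until the coefficient of variation of unmasked marginals drops below
    ``tol``.  The output total is rescaled to the input total, so ICE
    preserves both total and zero pattern.

    ``scope`` is ``"genome"`` (balance cis+trans jointly, the default) or
    ``"cis"`` (balance each chromosome's cis block independently).
    """
    if scope not in ("genome", "cis"):
        raise ValueError("scope must be 'genome' or 'cis'")
    if scope == "cis":
        dense = np.zeros((a.layout.n_bins, a.layout.n_bins))
        weights = np.full(a.layout.n_bins, np.nan)
        full = a.dense()
        for chrom in a.layout.chrom_names:
            sl = a.layout.chrom_slice(chrom)
            block = full[sl, sl]
            if block.sum() == 0:
                continue
            bal, w = _ice_dense(block, max_iter, tol, low_cov_quantile)
            dense[sl, sl] = bal
            weights[sl] = w
        out = ContactMatrix.from_dense(a.layout, dense, balanced=True, weights=weights)
        return out
    bal, w = _ice_dense(a.dense(), max_iter, tol, low_cov_quantile)
    return ContactMatrix.from_dense(a.layout, bal, balanced=True, weights=w)


def _ice_dense(dense: np.ndarray, max_iter, tol, low_cov_quantile):
    marg = dense.sum(axis=1)
    nz = marg[marg > 0]
    if nz.size == 0:
        raise ValueError("no bins with coverage; cannot balance")
    cutoff = np.quantile(nz, low_cov_quantile, method="lower")
    # slack keeps already-balanced marginals (equal up to tol) unmasked,
    # making balancing idempotent
    mask = marg >= cutoff * (1.0 - max(10 * tol, 1e-4))
    if not mask.any():
        raise ValueError("all bins masked; cannot balance")
    total_in = dense.sum()
    work = dense.copy()
    work[~mask, :] = 0.0
    work[:, ~mask] = 0.0
    if work.sum() == 0:
        raise ValueError("masked matrix is empty; cannot balance")
    w = np.ones(dense.shape[0])
    for _ in range(max_iter):
        m = work.sum(axis=1)[mask]
        mean = m.mean()
        if mean == 0:
            raise ValueError("degenerate matrix during balancing")
        cv = m.std() / mean
        if cv < tol:
            break
        b = np.ones(dense.shape[0])
        b[mask] = work.sum(axis=1)[mask] / mean
        work = work / np.outer(b, b)
        work[~mask, :] = 0.0
        work[:, ~mask] = 0.0
        w[mask] *= b[mask]
    work *= total_in / work.sum()
    weights = np.where(mask, w, np.nan)
    return work, weights


# -- CNV ---------------------------------------------------------------


@dataclass
class CNVResult:
    """Per-chromosome copy-number estimate from Hi-C marginal ratios."""

    table: pd.DataFrame  # chrom, median_log2, copy_ratio, call

    def call(self, chrom: str) -> str:
        return self.table.set_index("chrom").loc[chrom, "call"]

    def copy_ratio(self, chrom: str) -> float:
        return float(self.table.set_index("chrom").loc[chrom, "copy_ratio"])


def infer_cnv(
    test: ContactMatrix,
    ref: ContactMatrix,
    pseudocount: float = 1.0,
    call_window: float = 0.15,
) -> CNVResult:
    """Chromosome-level copy-ratio estimate of ``test`` relative to ``ref``.

    Both matrices are depth-normalized to a common total first, making
    the result invariant to global scaling.  Per-bin log2 marginal ratios
    (with pseudocount) are summarized by their per-chromosome median; a
    chromosome is called ``trisomic`` when the median lies within
    ``call_window`` of log2(1.5), ``disomic`` within ``call_window`` of 0,
    else ``other``.  Bins with zero marginal in the reference are skipped.
    """
    if test.layout != ref.layout:
        raise ValueError("test and reference layouts differ")
    target = 1e7
    mt = marginals(depth_normalize(test, target)).values
    mr = marginals(depth_normalize(ref, target)).values
    codes = test.layout.bin_chrom_codes()
    rows = []
    for ci, chrom in enumerate(test.layout.chrom_names):
        sel = (codes == ci) & (mr > 0)
        if not sel.any():
            rows.append((chrom, np.nan, np.nan, "other"))
            continue
        log2r = np.log2((mt[sel] + pseudocount) / (mr[sel] + pseudocount))
        med = float(np.median(log2r))
        ratio = 2.0**med
        if abs(med - np.log2(1.5)) <= call_window:
            call = "trisomic"
        elif abs(med) <= call_window:
            call = "disomic"
        else:
            call = "other"
        rows.append((chrom, med, ratio, call))
    return CNVResult(
        pd.DataFrame(rows, columns=["chrom", "median_log2", "copy_ratio", "call"])
    )


# -- decay & correlation ----------------------------------------------


def decay_curve(a: ContactMatrix) -> pd.DataFrame:
    """Mean cis contact per bin distance, normalized to sum 1 over d >= 1.

    Returns a table with columns ``distance`` (bins), ``mean_count`` and
    ``prob`` (the normalized curve).
    """
    n_max = max(
        -(-l // a.layout.bin_size) for l in a.layout.chrom_lengths
    )
    sums = np.zeros(n_max)
    npairs = np.zeros(n_max)
    for chrom in a.layout.chrom_names:
        block = a.cis_dense(chrom)
        nb = block.shape[0]
        for d in range(1, nb):
            sums[d] += np.trace(block, offset=d)
            npairs[d] += nb - d
    if npairs[1:].sum() == 0:
        raise ValueError("layout has no cis bin pairs at distance >= 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(npairs > 0, sums / np.maximum(npairs, 1), np.nan)
    valid = np.arange(n_max) >= 1
    norm = np.nansum(mean[valid])
    prob = np.where(valid & ~np.isnan(mean), mean / norm, np.nan)
    return pd.DataFrame(
        {"distance": np.arange(n_max), "mean_count": mean, "prob": prob}
    ).iloc[1:]


def matrix_correlation(a: ContactMatrix, b: ContactMatrix) -> float:
    """Pearson correlation of two matrices' upper-triangle entries.

    Both matrices are depth-normalized to a common total before
    comparison.
    """
    if a.layout != b.layout:
        raise ValueError("matrices must share a layout")
    target = 1e7
    ua = depth_normalize(a, target).upper.toarray()
    ub = depth_normalize(b, target).upper.toarray()
    iu = np.triu_indices(a.layout.n_bins)
    va, vb = ua[iu], ub[iu]
    return float(np.corrcoef(va, vb)[0, 1])
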