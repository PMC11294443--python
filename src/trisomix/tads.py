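"""Insulation scores, TAD boundary calling and domain statistics.

TAD boundaries appear as local minima of the insulation score: the mean
contact frequency in a square window sliding along the matrix diagonal
(computed here on balanced 40-kb matrices with a 500-kb window by
convention).  Regions between consecutive boundaries are TADs; domains
shorter than 200 kb are discarded.  Each domain carries a compaction
score — the proportion of its cis contacts that stay inside it — and
boundary sets from two samples are compared by nearest-boundary
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrix import ContactMatrix

__all__ = [
    "InsulationTrack",
    "TADSet",
    "insulation_track",
    "call_boundaries",
    "assemble_tads",
    "compaction_score",
    "boundary_conservation",
]


@dataclass
class InsulationTrack:
    """Per-bin raw window mean and log2-normalized insulation score.

    The normalized score is log2(raw / chromosome mean raw); it is
    defined only where the full window fits inside the chromosome, and
    is invariant to global matrix scaling.
    """

    layout: GenomeLayout
    raw: np.ndarray
    score: np.ndarray
    window_bp: int

    def for_chrom(self, chrom: str) -> np.ndarray:
        return self.score[self.layout.chrom_slice(chrom)]


def insulation_track(matrix: ContactMatrix, window_bp: int = 500_000) -> InsulationTrack:
    """Insulation score per bin from a balanced cis matrix.

    For bin b the raw value is the mean contact over the square window
    (b-w..b-1) x (b+1..b+w), with w = window_bp // bin_size.  Bins where
    the window does not fit (chromosome ends) are NaN, never
    extrapolated; chromosomes shorter than 2w+1 bins are fully masked.
    """
    lay = matrix.layout
    w = max(1, window_bp // lay.bin_size)
    raw = np.full(lay.n_bins, np.nan)
    score = np.full(lay.n_bins, np.nan)
    dense = matrix.dense()
    for chrom in lay.chrom_names:
        sl = lay.chrom_slice(chrom)
        block = dense[sl, sl]
        n = block.shape[0]
        if n < 2 * w + 1:
            continue
        vals = np.full(n, np.nan)
        for b in range(w, n - w):
            win = block[b - w : b, b + 1 : b + w + 1]
            vals[b] = win.mean()
        chrom_mean = np.nanmean(vals)
        if not np.isfinite(chrom_mean) or chrom_mean <= 0:
            continue
        raw[sl] = vals
        with np.errstate(divide="ignore", invalid="ignore"):
            score[sl] = np.log2(vals / chrom_mean)
    return InsulationTrack(lay, raw, score, window_bp)


def _local_extrema(x: np.ndarray, kind: str) -> np.ndarray:
    """Indices of strict-or-plateau local minima/maxima of a 1D array."""
    n = len(x)
    out = []
    cmp = np.less_equal if kind == "min" else np.greater_equal
    strict = np.less if kind == "min" else np.greater
    for i in range(1, n - 1):
        # extrema need both neighbours defined: edges of the defined
        # region (chromosome ends under the insulation window) are not
        # candidates
        if np.isnan(x[i]) or np.isnan(x[i - 1]) or np.isnan(x[i + 1]):
            continue
        left, right = x[i - 1], x[i + 1]
        if cmp(x[i], left) and cmp(x[i], right) and (strict(x[i], left) or strict(x[i], right)):
            out.append(i)
    return np.array(out, dtype=int)


def call_boundaries(
    track: InsulationTrack,
    delta_window_bp: int = 200_000,
    min_depth: float = 0.1,
) -> dict[str, np.ndarray]:
    """TAD boundaries as qualifying local minima of the insulation score.

    A bin is a boundary if it is the minimum within +/- delta_window and
    its score lies at least ``min_depth`` (log2 units) below the higher
    of the two nearest flanking local maxima.  Returns chromosome-local
    bin indices per chromosome (may be empty).
    """
    lay = track.layout
    dw = max(1, delta_window_bp // lay.bin_size)
    out: dict[str, np.ndarray] = {}
    for chrom in lay.chrom_names:
        x = track.for_chrom(chrom)
        n = len(x)
        maxima = _local_extrema(x, "max")
        bounds = []
        for b in _local_extrema(x, "min"):
            lo, hi = max(0, b - dw), min(n, b + dw + 1)
            win = x[lo:hi]
            if not np.isfinite(x[b]) or np.nanmin(win) < x[b]:
                continue
            left_max = maxima[maxima < b]
            right_max = maxima[maxima > b]
            flank = []
            if left_max.size:
                flank.append(x[left_max[-1]])
            if right_max.size:
                flank.append(x[right_max[0]])
            if not flank:
                continue
            if max(flank) - x[b] >= min_depth:
                bounds.append(b)
        # collapse plateau/adjacent duplicates within the delta window
        dedup = []
        for b in bounds:
            if dedup and b - dedup[-1] <= dw and np.isclose(x[b], x[dedup[-1]]):
                continue
            dedup.append(b)
        out[chrom] = np.array(dedup, dtype=int)
    return out


@dataclass
class TADSet:
    """Ordered non-overlapping domains with compaction scores.

    ``domains`` columns: chrom, start_bin, end_bin (chromosome-local,
    half-open), start, end (bp), length, whole_chromosome flag and,
    after :func:`compaction_score` annotation, the score.
    """

    layout: GenomeLayout
    boundaries: dict[str, np.ndarray]
    domains: pd.DataFrame


def assemble_tads(
    boundaries: dict[str, np.ndarray],
    layout: GenomeLayout,
    min_tad_len: int = 200_000,
) -> TADSet:
    """Domains between consecutive boundaries, dropping those < min_tad_len.

    A chromosome with no called boundaries yields one flagged
    whole-chromosome domain so downstream joins never silently drop
    chromosomes.
    """
    rows = []
    for chrom in layout.chrom_names:
        sl = layout.chrom_slice(chrom)
        n = sl.stop - sl.start
        bs = np.asarray(sorted(boundaries.get(chrom, [])), dtype=int)
        if bs.size == 0:
            length = layout.chrom_lengths[layout.chrom_names.index(chrom)]
            rows.append((chrom, 0, n, 0, length, length, True))
            continue
        edges = bs.tolist()
        for a, b in zip(edges[:-1], edges[1:]):
            start_bp = a * layout.bin_size
            end_bp = min(b * layout.bin_size, layout.chrom_lengths[layout.chrom_names.index(chrom)])
            length = end_bp - start_bp
            if length >= min_tad_len:
                rows.append((chrom, a, b, start_bp, end_bp, length, False))
    domains = pd.DataFrame(
        rows,
        columns=["chrom", "start_bin", "end_bin", "start", "end", "length", "whole_chromosome"],
    )
    return TADSet(layout, {c: np.asarray(sorted(boundaries.get(c, [])), int) for c in layout.chrom_names}, domains)


def compaction_score(
    matrix: ContactMatrix,
    chrom: str,
    start_bin: int,
    end_bin: int,
    include_trans: bool = False,
) -> float:
    """Fraction of a domain's contacts that stay inside the domain.

    within = contacts with both ends in [start_bin, end_bin) of
    ``chrom``; involving = within + contacts with exactly one end in the
    domain (cis only by default; ``include_trans`` adds trans ends).
    NaN when the domain is involved in no contacts.
    """
    lay = matrix.layout
    sl = lay.chrom_slice(chrom)
    lo, hi = sl.start + start_bin, sl.start + end_bin
    if hi > sl.stop or start_bin < 0 or end_bin <= start_bin:
        raise ValueError("domain outside chromosome")
    dense = matrix.dense()
    dom = np.arange(lo, hi)
    block = dense[np.ix_(dom, dom)]
    within = np.triu(block).sum()
    if include_trans:
        other = np.setdiff1d(np.arange(lay.n_bins), dom)
    else:
        other = np.setdiff1d(np.arange(sl.start, sl.stop), dom)
    cross = dense[np.ix_(dom, other)].sum()
    involving = within + cross
    if involving == 0:
        return float("nan")
    return float(within / involving)


def annotate_compaction(tads: TADSet, matrix: ContactMatrix, include_trans: bool = False) -> TADSet:
    """Add a compaction-score column to a TADSet's domain table."""
    scores = [
        compaction_score(matrix, r.chrom, r.start_bin, r.end_bin, include_trans)
        for r in tads.domains.itertuples()
    ]
    dom = tads.domains.copy()
    dom["compaction"] = scores
    return TADSet(tads.layout, tads.boundaries, dom)


def boundary_conservation(
    a: np.ndarray,
    b: np.ndarray,
    tolerances_bins=(0, 1, 2),
) -> pd.DataFrame:
    """Fraction of boundaries matched across two samples, per tolerance.

    For each tolerance t the fraction of a-boundaries whose nearest
    b-boundary lies within t bins, and symmetrically b vs a.  NaN when
    the queried set is empty.
    """
    a = np.asarray(sorted(a), dtype=float)
    b = np.asarray(sorted(b), dtype=float)

    def frac(src, dst, t):
        if src.size == 0:
            return float("nan")
        if dst.size == 0:
            return 0.0
        d = np.min(np.abs(src[:, None] - dst[None, :]), axis=1)
        return float((d <= t).mean())

    rows = [
        {"tolerance_bins": t, "a_in_b": frac(a, b, t), "b_in_a": frac(b, a, t)}
        for t in tolerances_bins
    ]
    return pd.DataFrame(rows)
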