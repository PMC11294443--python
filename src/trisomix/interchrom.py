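"""Inter-chromosomal proximity scores and interaction fractions.

Both statistics are computed on *raw* (unbalanced) matrices, since
balancing absorbs exactly the marginal structure they measure.

Proximity score: for chromosomes i, j with observed trans contact count
O_ij (symmetric, zero diagonal), let N_i be the total trans contacts
involving chromosome i and N = sum_i N_i (each contact counted at both
ends — the reading under which the expected-proportion matrix sums to
less than 1).  The expected proportion is R_ij = (N_i/N)(N_j/N); R is
rescaled so the expected matrix E_ij = R_ij / R_sum * O_sum matches the
observed total, and the score is P_ij = log2(O_ij / E_ij).  P is
invariant to global depth scaling.

ICF (inter-chromosomal interaction fraction): per bin, trans contacts
over trans + cis contacts, in [0, 1]; high-ICF regions are those most
exposed to other chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .layout import BinTrack
from .matrix import ContactMatrix

__all__ = [
    "InterchromCounts",
    "ProximityResult",
    "interchrom_counts",
    "proximity_scores",
    "icf_track",
    "icf_group_stats",
    "density_association",
]


@dataclass
class InterchromCounts:
    """Symmetric chromosome-pair observed trans count matrix.

    ``N_i`` are row sums of O; ``N = sum(N_i) = O.sum()``.
    """

    chrom_names: tuple[str, ...]
    O: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.O, self.O.T):
            raise ValueError("O must be symmetric")
        if np.diag(self.O).any():
            raise ValueError("O must have a zero diagonal")
        if (self.O < 0).any():
            raise ValueError("O must be non-negative")

    @property
    def N_i(self) -> np.ndarray:
        return self.O.sum(axis=1)

    @property
    def N(self) -> float:
        return float(self.N_i.sum())


def interchrom_counts(matrix: ContactMatrix) -> InterchromCounts:
    """Aggregate trans contacts into a chromosome-pair count matrix.

    Each unordered bin pair is counted once and mirrored into both
    triangles of O.  Raw matrices should be used; balanced input raises.
    """
    if matrix.balanced:
        raise ValueError("inter-chromosomal counts require a raw matrix")
    lay = matrix.layout
    if lay.n_chroms < 2:
        raise ValueError("need at least two chromosomes")
    codes = lay.bin_chrom_codes()
    coo = matrix.upper.tocoo()
    ci, cj = codes[coo.row], codes[coo.col]
    trans = ci != cj
    O = np.zeros((lay.n_chroms, lay.n_chroms))
    np.add.at(O, (ci[trans], cj[trans]), coo.data[trans])
    O = O + O.T
    return InterchromCounts(tuple(lay.chrom_names), O)


@dataclass
class ProximityResult:
    """Expected proportions R, expected counts E and log2 O/E scores P.

    P entries for chromosome pairs with no observed contacts are NaN
    (masked) rather than -inf.
    """

    chrom_names: tuple[str, ...]
    O: np.ndarray
    R: np.ndarray
    R_sum: float
    E: np.ndarray
    P: np.ndarray

    def score(self, chrom_a: str, chrom_b: str) -> float:
        i = self.chrom_names.index(chrom_a)
        j = self.chrom_names.index(chrom_b)
        return float(self.P[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.chrom_names)):
            for j in range(i + 1, len(self.chrom_names)):
                rows.append(
                    {
                        "chrom_a": self.chrom_names[i],
                        "chrom_b": self.chrom_names[j],
                        "observed": self.O[i, j],
                        "expected": self.E[i, j],
                        "proximity": self.P[i, j],
                    }
                )
        return pd.DataFrame(rows)


def proximity_scores(c: InterchromCounts, pseudocount: float = 0.0) -> ProximityResult:
    """Observed/expected proximity scores for every chromosome pair.

    The expected matrix conserves the observed total exactly
    (sum_{i!=j} E_ij = O_sum), and R_sum = 1 - sum_i (N_i/N)^2 < 1
    whenever at least two chromosomes have trans contacts.
    """
    O = c.O.astype(float)
    if pseudocount:
        O = O + pseudocount
        np.fill_diagonal(O, 0.0)
    N_i = O.sum(axis=1)
    N = N_i.sum()
    if N == 0:
        raise ValueError("no inter-chromosomal contacts")
    if (N_i > 0).sum() < 2:
        raise ValueError("need >= 2 chromosomes with trans contacts")
    share = N_i / N
    R = np.outer(share, share)
    np.fill_diagonal(R, 0.0)
    R_sum = R.sum()
    O_sum = O.sum()
    E = R / R_sum * O_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.log2(O / E)
    P[(O == 0) | (E == 0)] = np.nan
    np.fill_diagonal(P, np.nan)
    return ProximityResult(c.chrom_names, c.O, R, float(R_sum), E, P)


def icf_track(matrix: ContactMatrix) -> pd.DataFrame:
    """Per-bin inter-chromosomal interaction fraction on a raw matrix.

    Returns a table with columns ``inter``, ``intra`` (diagonal counted
    once) and ``icf`` = inter/(inter+intra); zero-coverage bins get NaN.
    """
    if matrix.balanced:
        raise ValueError("ICF requires a raw matrix")
    lay = matrix.layout
    codes = lay.bin_chrom_codes()
    sym = matrix.sym()
    total = np.asarray(sym.sum(axis=1)).ravel()
    # intra: zero out trans entries chromosome by chromosome
    intra = np.zeros(lay.n_bins)
    dense = matrix.dense()
    for chrom in lay.chrom_names:
        sl = lay.chrom_slice(chrom)
        intra[sl] = dense[sl, sl].sum(axis=1)
    inter = total - intra
    with np.errstate(invalid="ignore", divide="ignore"):
        icf = np.where(total > 0, inter / total, np.nan)
    return pd.DataFrame(
        {
            "chrom": lay.bin_table["chrom"],
            "start": lay.bin_table["start"],
            "end": lay.bin_table["end"],
            "inter": inter,
            "intra": intra,
            "icf": icf,
        }
    )


def icf_as_bintrack(matrix: ContactMatrix) -> BinTrack:
    tab = icf_track(matrix)
    return BinTrack(matrix.layout, tab["icf"].to_numpy(), name="icf")


def icf_group_stats(
    icf: np.ndarray,
    groups: np.ndarray,
    order: list | None = None,
) -> pd.DataFrame:
    """Summarize ICF distributions per group with adjacent-group tests.

    ``groups`` assigns each bin a label (NaN-ICF bins are dropped).  The
    output has one row per group in ``order`` (or sorted unique labels):
    n, median, mean, and the two-sided Wilcoxon rank-sum p-value against
    the previous group; groups with fewer than 2 bins are flagged.
    """
    icf = np.asarray(icf, float)
    groups = np.asarray(groups)
    ok = ~np.isnan(icf) & ~pd.isna(groups)
    icf, groups = icf[ok], groups[ok]
    labels = order if order is not None else sorted(pd.unique(groups))
    rows, prev_vals = [], None
    for lab in labels:
        vals = icf[groups == lab]
        flagged = len(vals) < 2
        p = np.nan
        if prev_vals is not None and not flagged and len(prev_vals) >= 2:
            if np.array_equal(np.sort(vals), np.sort(prev_vals)):
                p = 1.0
            else:
                p = float(scipy.stats.ranksums(vals, prev_vals).pvalue)
        rows.append(
            {
                "group": lab,
                "n": len(vals),
                "median": float(np.median(vals)) if len(vals) else np.nan,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "p_vs_previous": p,
                "flagged": flagged,
            }
        )
        prev_vals = vals
    return pd.DataFrame(rows)


def expression_groups(fpkm: np.ndarray, low: float = 10.0, high: float = 100.0) -> np.ndarray:
    """Assign low/middle/high expression classes at FPKM 10/100 cut points."""
    fpkm = np.asarray(fpkm, float)
    out = np.where(fpkm < low, "low", np.where(fpkm > high, "high", "middle"))
    return np.where(np.isnan(fpkm), None, out)


def density_association(
    p: ProximityResult,
    density: dict[str, float] | pd.Series,
    focal: str,
) -> dict[str, float]:
    """Correlate the focal chromosome's proximity scores with gene density.

    Pearson and Spearman correlations over all partner chromosomes j of
    P(focal, j) against per-chromosome gene density.  Requires >= 3
    partners with defined scores; constant density gives NaN (flagged).
    """
    if focal not in p.chrom_names:
        raise ValueError(f"focal chromosome {focal!r} not present")
    i = p.chrom_names.index(focal)
    xs, ys = [], []
    for j, name in enumerate(p.chrom_names):
        if name == focal or not np.isfinite(p.P[i, j]):
            continue
        d = density[name] if name in density else np.nan
        if np.isfinite(d):
            xs.append(d)
            ys.append(p.P[i, j])
    if len(xs) < 3:
        raise ValueError("need at least 3 partner chromosomes with scores")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.std(xs) == 0 or np.std(ys) == 0:
        return {"pearson": np.nan, "spearman": np.nan, "n": len(xs)}
    return {
        "pearson": float(scipy.stats.pearsonr(xs, ys).statistic),
        "spearman": float(scipy.stats.spearmanr(xs, ys).statistic),
        "n": len(xs),
    }
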