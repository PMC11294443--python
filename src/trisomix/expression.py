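"""Expression quantification, differential expression and dosage effects.

FPKM values follow count / (exon length in kb x library size in
millions).  Differential expression uses a transparent, auditable test:
median-of-ratios size factors, log2 fold change of normalized condition
means, a two-sided Welch t-test on log2(normalized count + 1), and
Benjamini-Hochberg correction; genes pass at fold change > 1.2 (either
direction) and FDR < 0.05.  The dosage summary quantifies how far the
trisomic chromosome's median fold change falls short of the 1.5-fold
expected from three copies versus two, as a compensation index
c = (1.5 - median FC) / 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .layout import validate_gene_table

__all__ = [
    "compute_fpkm",
    "filter_expressed",
    "size_factors",
    "call_degs",
    "shared_degs",
    "chromosome_expression",
    "fc_by_chromosome",
    "DosageSummary",
]

FC_THRESHOLD = 1.2
FDR_THRESHOLD = 0.05


def compute_fpkm(counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """FPKM per gene and sample: count / (exon kb x library millions).

    Library size is the per-sample total of assigned counts.  Gene order
    in ``genes`` must match the count table index.
    """
    validate_gene_table(genes)
    if len(genes) != len(counts):
        raise ValueError("gene table and count table lengths differ")
    exon_kb = genes["exon_length_bp"].to_numpy() / 1e3
    if (exon_kb <= 0).any():
        raise ValueError("zero-length gene")
    lib_m = counts.sum(axis=0).to_numpy() / 1e6
    if (lib_m <= 0).any():
        raise ValueError("library size must be positive")
    fpkm = counts.to_numpy() / exon_kb[:, None] / lib_m[None, :]
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def filter_expressed(
    a_fpkm: pd.DataFrame | pd.Series,
    b_fpkm: pd.DataFrame | pd.Series,
    min_fpkm: float = 1.0,
) -> pd.Index:
    """Genes expressed (FPKM >= min) in at least one of two conditions.

    Condition-level FPKM is the mean over replicates; genes below the
    threshold in *both* conditions are removed (low FPKM is usually
    noise rather than true expression).
    """
    a = a_fpkm.mean(axis=1) if isinstance(a_fpkm, pd.DataFrame) else a_fpkm
    b = b_fpkm.mean(axis=1) if isinstance(b_fpkm, pd.DataFrame) else b_fpkm
    keep = (a >= min_fpkm) | (b >= min_fpkm)
    return a.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = geometric mean gene-wise).

    Genes with a zero count in any sample are excluded from the
    reference, as in the standard RNA-seq formulation.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    log_geo = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


@dataclass
class DEGResult:
    """Per-gene fold change, p-values and DEG flags for one comparison."""

    table: pd.DataFrame  # gene-indexed: log2fc, fc, pvalue, padj, direction, deg
    condition_a: str = "a"
    condition_b: str = "b"

    @property
    def up(self) -> pd.Index:
        t = self.table
        return t.index[t["deg"] & (t["direction"] == "up")]

    @property
    def down(self) -> pd.Index:
        t = self.table
        return t.index[t["deg"] & (t["direction"] == "down")]


def call_degs(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> DEGResult:
    """Differential expression of condition b relative to condition a.

    Both conditions need >= 2 replicates (no within-group variance
    estimate is possible otherwise).  Normalized counts are raw counts
    over joint median-of-ratios size factors; fold change is the ratio
    of normalized means (b over a, with a half-count pseudovalue when a
    mean is zero); the p-value is a two-sided Welch t-test on
    log2(normalized + 1); FDR is Benjamini-Hochberg.  A gene is a DEG
    when FC > threshold or FC < 1/threshold and FDR < threshold.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    joint = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(joint)
    norm = joint / sf
    na, nb = counts_a.shape[1], counts_b.shape[1]
    norm_a, norm_b = norm.iloc[:, :na], norm.iloc[:, na:]
    mean_a = norm_a.mean(axis=1).to_numpy()
    mean_b = norm_b.mean(axis=1).to_numpy()
    pseudo = 0.5
    fc = (mean_b + np.where(mean_a == 0, pseudo, 0)) / np.where(
        mean_a == 0, pseudo, mean_a
    )
    fc = np.where((mean_a == 0) & (mean_b == 0), 1.0, fc)
    log_a = np.log2(norm_a.to_numpy() + 1)
    log_b = np.log2(norm_b.to_numpy() + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    padj = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(fc >= 1, "up", "down")
    deg = ((fc > fc_threshold) | (fc < 1 / fc_threshold)) & (padj < fdr_threshold)
    table = pd.DataFrame(
        {
            "fc": fc,
            "log2fc": np.log2(fc),
            "pvalue": pvals,
            "padj": padj,
            "direction": direction,
            "deg": deg,
        },
        index=joint.index,
    )
    return DEGResult(table)


def shared_degs(results: list[DEGResult], min_support: int = 2) -> dict[str, pd.Index]:
    """Genes called DEG in the same direction in >= min_support comparisons.

    Genes up in one comparison and down in another are excluded from
    both shared sets and reported under ``discordant``.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 comparisons")
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for r in results:
        for g in r.up:
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in r.down:
            down_counts[g] = down_counts.get(g, 0) + 1
    ever_up, ever_down = set(up_counts), set(down_counts)
    discordant = ever_up & ever_down
    shared_up = {g for g, n in up_counts.items() if n >= min_support} - discordant
    shared_down = {g for g, n in down_counts.items() if n >= min_support} - discordant
    return {
        "up": pd.Index(sorted(shared_up)),
        "down": pd.Index(sorted(shared_down)),
        "discordant": pd.Index(sorted(discordant)),
    }


def chromosome_expression(fpkm: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Chromosome-wide expression: mean FPKM over genes on each chromosome."""
    mean_fpkm = fpkm.mean(axis=1)
    chrom = pd.Series(genes["chrom"].to_numpy(), index=fpkm.index)
    return mean_fpkm.groupby(chrom).mean()


@dataclass
class DosageSummary:
    """Per-chromosome fold-change distributions and the compensation index.

    The compensation index c = (1.5 - median FC of trisomic-chromosome
    genes) / 0.5 is 0 under a full dosage effect (median FC 1.5) and 1
    under complete compensation (median FC 1.0); NaN when no chromosome
    is marked trisomic.
    """

    per_chromosome: pd.DataFrame  # chrom, n_genes, median_fc, mean_fc
    fc: pd.Series  # per-gene fold change (filtered genes)
    trisomic_chrom: str | None

    @property
    def trisomic_median_fc(self) -> float:
        if self.trisomic_chrom is None:
            return float("nan")
        t = self.per_chromosome.set_index("chrom")
        return float(t.loc[self.trisomic_chrom, "median_fc"])

    @property
    def compensation_index(self) -> float:
        return (1.5 - self.trisomic_median_fc) / 0.5


def fc_by_chromosome(
    counts_ts: pd.DataFrame,
    counts_wt: pd.DataFrame,
    genes: pd.DataFrame,
    trisomic_chrom: str | None = None,
    min_fpkm: float = 1.0,
) -> DosageSummary:
    """Fold-change distribution per chromosome and the dosage summary.

    Applies the expressed-gene filter (condition-mean FPKM >= min in at
    least one condition), computes size-factor-normalized per-gene fold
    changes (trisomic over wild type), and summarizes them per
    chromosome.  Chromosomes with no expressed genes are absent from the
    table (masked).
    """
    validate_gene_table(genes)
    fpkm_wt = compute_fpkm(counts_wt, genes)
    fpkm_ts = compute_fpkm(counts_ts, genes)
    keep = filter_expressed(fpkm_ts, fpkm_wt, min_fpkm=min_fpkm)
    joint = pd.concat([counts_wt.loc[keep], counts_ts.loc[keep]], axis=1)
    sf = size_factors(joint)
    norm = joint / sf
    nw = counts_wt.shape[1]
    mean_wt = norm.iloc[:, :nw].mean(axis=1)
    mean_ts = norm.iloc[:, nw:].mean(axis=1)
    ok = mean_wt > 0
    fc = (mean_ts[ok] / mean_wt[ok]).rename("fc")
    chrom = pd.Series(genes["chrom"].to_numpy(), index=counts_wt.index).loc[fc.index]
    grouped = fc.groupby(chrom)
    per_chrom = pd.DataFrame(
        {
            "n_genes": grouped.size(),
            "median_fc": grouped.median(),
            "mean_fc": grouped.mean(),
        }
    ).reset_index(names="chrom")
    return DosageSummary(per_chrom, fc, trisomic_chrom)
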