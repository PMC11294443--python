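# Methods

This note documents the models behind `trisomix`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing
results.

## Coordinate conventions

All coordinates are 0-based, half-open. A genome layout assigns
consecutive global bin indices ordered by chromosome, then start; the
last bin of a chromosome may be shorter than the bin size. Contact
matrices are stored as their upper triangle and queried symmetrically;
the diagonal is counted once in marginals and totals. Triplet files may
contain either triangle on input — both orientations are folded into
the upper triangle by summation (duplicates produce a warning), which
makes ingestion tolerant of the several conventions in circulation.
Genes are assigned to bins by their start coordinate only, so gene
density is a deterministic count (genes/Mb) rather than a coverage
fraction.

## Normalization

Raw matrices are used for all inter-chromosomal statistics (proximity
scores, ICF), because matrix balancing equalizes exactly the marginal
structure those statistics measure. Balanced matrices are used for all
cis structure (compartments, TADs).

**ICE balancing** iterates `w_i ← w_i / (marginal_i / mean marginal)`
until the coefficient of variation of unmasked marginals falls below
`tol = 1e-5` or 200 iterations. Bins whose coverage is below the 2%
quantile of nonzero marginals (taken with lower interpolation, and with
a small relative slack so that an already-balanced matrix re-masks
nothing and the operation is idempotent) are masked first, along with
zero-coverage bins. The output is rescaled to the input total, so
balancing preserves the matrix total and the zero pattern outside the
mask. Balancing is genome-wide (cis + trans) by default with a
per-chromosome `scope="cis"` alternative; the literature uses both and
downstream cis analyses re-extract cis blocks either way.

**Copy-number inference** replaces segmentation-based CNV callers with
a transparent marginal-ratio method: both matrices are depth-normalized
to a common total, per-bin log2 marginal ratios (pseudocount 1) are
summarized by their per-chromosome median, and a chromosome is called
trisomic when the median falls within ±0.15 of log2 1.5 (disomic within
±0.15 of 0, otherwise "other"). Because normalization to a common depth
absorbs part of the inflation the extra chromosome causes, the trisomic
copy-ratio estimate sits slightly below 1.5 — about 1.38 on a genome
where the trisomic chromosome carries ~10% of all contacts — which is
well inside the call window on genomes of realistic chromosome number.
The method is only meant to confirm a known whole-chromosome trisomy,
not to discover focal CNVs.

## Compartments

Per chromosome, the cis matrix is transformed to observed/expected by
dividing each entry by the mean of its bin-distance diagonal (computed
over unmasked bins; zero-mean diagonals stay undefined). The Pearson
correlation matrix of the O/E columns is eigendecomposed and the
leading component taken, at 500-kb bins by default. Because the
compartment contact term depends only on sign *products*, the
eigenvector sign is arbitrary; A/B identity is anchored by gene
density: the sign whose bins have the higher mean density is A. On
short chromosomes the compartment signal occasionally lands in the
second component, so of the two leading components the one with the
larger |correlation| to gene density is used (logged when the second
wins).

Confidence flag: a component that does not correlate significantly
with gene density (two-sided Pearson p, Bonferroni-corrected by 2 for
the two-component selection, above 0.01) cannot be confidently
oriented; the chromosome is flagged low-confidence. This is exactly
the situation a compartment-free matrix produces — simpler eigenvalue
criteria turned out not to separate signal from the structured noise
that balancing and shared-entry effects induce in O/E correlation
matrices of short chromosomes.

The segregation score per chromosome sums cis contacts over bin pairs
at genomic distance ≥ 2 Mb (|start_i − start_j| ≥ 2,000,000; "within
2 Mb" is read as strictly-closer-excluded), partitioned into AA, BB and
AB by label pair; the score is AB/(AA+BB), undefined when AA+BB = 0.
The switch fraction between two samples is bin-weighted (the fraction
of jointly labeled bins whose label differs); a segment-weighted
variant would weight long compartment blocks differently but is not
implemented.

## TADs

Insulation for bin b is the mean contact in the square window
(b−w…b−1) × (b+1…b+w) with w = window // bin size; the default 500-kb
window on 40-kb bins truncates to w = 12 (480 kb effective). Bins where
the window does not fit are masked, never extrapolated; chromosomes
shorter than 2w+1 bins are fully masked. The normalized score is
log2(raw / chromosome mean raw), which makes it invariant to global
matrix scaling.

A bin is a boundary when it is the minimum within ±200 kb and its score
lies at least 0.1 log2 units below the higher of the two nearest
flanking local maxima. Local extrema require both neighbours defined,
so the edges of the defined region cannot become spurious boundaries.
Window, delta-window and depth threshold follow common usage of
insulation-based callers on 40-kb matrices and are all exposed as
parameters. Domains are the intervals between consecutive boundaries;
domains shorter than 200 kb are dropped. A chromosome with no called
boundaries yields one whole-chromosome domain flagged as such, so
downstream joins never silently lose chromosomes.

The compaction score of a domain is within/(within + cross), where
"cross" counts cis contacts with exactly one end in the domain;
`include_trans=True` adds trans ends. Cis-only is the default because
balanced cis matrices are the substrate of TAD analysis, but the
convention visibly shifts the score, hence the toggle. Boundary
conservation between samples is reported symmetrically (a→b and b→a) at
tolerances 0, 1 and 2 bins by default, since "within one bin" is
ambiguous between distance 0 and distance ≤ 1.

## Inter-chromosomal statistics

For the proximity score, N is defined as Σ_i N_i, i.e. every trans
contact is counted at both of its ends, and equals the full symmetric
pair-matrix sum O_sum. Under this reading R_sum = 1 − Σ_i (N_i/N)² < 1
strictly whenever at least two chromosomes have trans contacts (it is
1 minus a sum of squares of shares that each lie strictly below 1),
and the expected matrix E = R/R_sum·O_sum conserves the observed total
exactly. Pairs with zero observed contacts yield masked (NaN) scores
rather than −inf; a pseudocount option exists but defaults off so the
printed formula stays exact. The score is invariant to global depth
scaling, and on simulations it absorbs the marginal inflation of a
trisomic chromosome almost entirely (WT/trisomic score matrices
correlate above 0.9 at default depth).

ICF is computed from raw counts at 1-Mb bins by default: per bin,
trans/(trans + cis) with the diagonal counted once in cis; bins with no
coverage are masked. Grouped ICF summaries use two-sided Wilcoxon
rank-sum tests between adjacent groups; expression classes cut at
FPKM 10 and 100, gene density at the median, compartments at the A/B
label.

## Expression

FPKM = count / (exon kb × library millions), with library size the
per-sample total of assigned counts. The expressed-gene filter keeps a
gene when its condition-mean FPKM is ≥ 1 in at least one of the two
conditions — values below 1 in both are treated as noise.

Differential expression is deliberately a transparent pluggable test
rather than a shrinkage-based NB-GLM: joint median-of-ratios size
factors, fold change of normalized condition means (half-count
pseudovalue when a mean is zero), two-sided Welch t on
log2(normalized + 1), Benjamini–Hochberg correction. The decision
thresholds — fold change > 1.2 (applied two-sidedly, i.e. FC > 1.2 or
FC < 1/1.2) and FDR < 0.05 — and the shared-DEG set logic (same
direction in ≥ 2 comparisons; genes discordant across comparisons are
excluded and reported separately) are where the scientific content
lives and are preserved exactly. At least two replicates per condition
are required, since no within-group variance is estimable otherwise.

The dosage summary reports per-chromosome fold-change distributions of
size-factor-normalized means and the compensation index
c = (1.5 − median FC_trisomic)/0.5, so c = 0 under a full dosage effect
and c = 1 under complete compensation. One known small bias: genes on
the trisomic chromosome enter the size-factor reference, which deflates
all fold changes by roughly half the trisomic gene fraction — about 2%
on a 20-chromosome genome — and this is visible as trisomic medians
near 1.47 rather than 1.50 in the recovery tests.

## Imaging

Masks live on a voxel grid with per-axis physical sizes (anisotropy is
supported throughout; confocal stacks commonly have ~0.4-µm z steps
against ~0.1-µm lateral pixels). Volumes are voxel counts times voxel
volume. The intermingling index is V_AB²/(V_A·V_B) — symmetric, 1 for
identical masks, 0 for disjoint ones, invariant to isotropic voxel
rescaling. Radial distance is the minimum, over territory surface
voxels (mask voxels with ≥ 1 false 6-neighbour), of the anisotropy-
aware Euclidean distance transform of the nucleus mask; the grid
boundary counts as membrane so that nuclei clipped by the field of view
behave sensibly. Spot-in-mask membership is floor(coordinate/voxel
size) per axis with no sub-voxel interpolation, matching segmentation-
mask semantics; spots outside the grid warn and are excluded.
Transcriptional intensity is always mask-restricted (spots over mask
volume) — never whole-nucleus — which also implements nucleolar
exclusion when the masks are chromosome paints. Nucleus-size
normalization divides volumes by nucleus volume and distances by the
nucleus equivalent-sphere diameter 2·(3V/4π)^(1/3). Pair statistics are
reported for the intersection (intermingling) and symmetric difference
(non-intermingling) regions; per-label and per-connected-component
aggregation are both available because real imaging counts territory
copies, not chromosomes.

## Synthetic data

The generators exist so that every downstream statistic has a planted
ground truth; all randomness flows from a single integer seed and fixed
seeds give bit-identical output.

**Hi-C.** Poisson counts with rate
λ_ij = Z·m_i·m_j·[cis: s^−α·(1+κ c_i c_j)·τ^[same TAD] | trans: π(chr_i, chr_j)],
where s is bin distance (s = 0 treated as s = 1, so the diagonal is
regular and downstream statistics that exclude it are unaffected),
α = 1 by default (fractal-globule-like decay), c_i ∈ {±1} the planted
compartment signs with strength κ ∈ [0, 1), τ ≥ 1 the TAD enrichment,
π a symmetric chromosome-pair preference and m_i the per-chromosome
copy-number multiplier. Trisomy is a bulk 1.5× multiplier on every
contact involving the chromosome — how bulk Hi-C pooled over homologs
sees copy number — not a per-homolog structural model. Z calibrates the
expected symmetric-matrix total to the requested depth, which mimics
sequencing to fixed depth: the trisomy inflates the chromosome's
*share*, not the total. The generator does not attempt realistic
karyotype-wide contact statistics, loops, or read-level output.

**Expression.** Negative-binomial counts (variance μ + αμ², sampled as
gamma-Poisson; α below 1e-12 falls back to Poisson) with a dosage
factor d = 1 + 0.5(1 − γ) on trisomic-chromosome genes: γ = 0 gives the
full 1.5-fold of three copies vs. two, γ = 1 complete compensation.
Baseline means are per-gene; a library factor scales each condition to
the requested library size. The default validation genome uses 20
chromosomes so trisomic genes are ~5% of the transcriptome, matching
the mouse situation; on genomes with few chromosomes the trisomic
fraction grows and the size-factor bias discussed above becomes
material. The generator has no batch effects, no gene-length bias, no
outlier genes and no trans-acting secondary response, so passing
recovery tests demonstrates correctness of the dosage arithmetic, not
robustness to those real-data phenomena.

**Imaging.** The nucleus is an ellipsoid (default semi-axes
4.0 × 4.0 × 3.8 µm on a 64 × 64 × 24 grid of 0.15 × 0.15 × 0.4 µm
voxels, i.e. an mESC-sized nucleus). Each territory is a blob: a
Gaussian distance kernel around its center plus smoothed uniform noise,
cut at the weight threshold that hits the target volume exactly
(equivalently, the top-k voxels by weight; k from the target volume),
clipped to the nucleus. Centers are explicit or placed on a ring whose
chord spacing is `overlap_offset`, which therefore controls pairwise
intermingling. Spots are voxelwise Poisson at `spot_rate_base` per µm³
inside the nucleus, multiplied by `spot_rate_intermingle` in voxels
covered by two or more territories, and placed uniformly within their
voxel — so simulator truth (exact mask volumes, overlap volumes and
per-mask spot counts) matches the analysis discretization exactly. How
disomic territory volumes contract in trisomic cells is not modelled;
territory volume is a free parameter.

## Validation problem sizes

The test suite runs the full recovery chain at deliberately small
scale: checkerboard compartments on two 50-Mb chromosomes at 500-kb
bins (depth 2×10⁶), TADs on one 10-Mb chromosome at 40-kb bins
(τ = 5, depth 2×10⁶), ICF on ten 2-Mb chromosomes (depth 10⁶ per
replicate, 20 replicates), and expression on 2000 genes with three
replicates per condition. These sizes keep the whole suite under a
minute while leaving the sampling-error margins comfortably inside the
asserted tolerances; the statistics themselves are size-agnostic.

## Known limitations

- The DEG test is a Welch t on log-transformed normalized counts; at
  very low counts or two replicates it is less powerful and less
  calibrated than shrinkage-based NB models. The test function is
  pluggable by design.
- Compartment calling returns a single PC per chromosome; no
  subcompartments, no saddle analysis.
- The TAD caller is single-scale insulation; no directionality index,
  no nested domains, no loops.
- CNV inference assumes whole-chromosome events.
- Proximity scores require a raw matrix; running them on balanced input
  raises rather than returning silently meaningless values.
- 1-Mb/100-kb analyses bin the genome directly at the requested
  resolution rather than aggregating 40-kb bins; with the half-open
  binning convention the two differ only at chromosome ends.
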