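"""Synthetic Hi-C, RNA-seq and 3D-imaging data with planted ground truth.

Every downstream statistic in the pipeline is tested against data whose
generative parameters are known exactly:

* Hi-C: Poisson counts over a rate surface combining power-law cis decay,
  a checkerboard A/B compartment term, TAD block enrichment, chromosome-
  pair trans preferences and a per-chromosome copy-number multiplier
  (1.5x models a trisomy as Hi-C sees it — bulk inflation of every
  contact involving the extra chromosome, pooled over homologs).
* Expression: negative-binomial gene counts where genes on the trisomic
  chromosome carry a dosage factor d = 1 + 0.5*(1 - gamma); gamma is the
  dosage-compensation parameter (gamma=0 gives the full 1.5-fold expected
  from three copies vs. two, gamma=1 none).
* Imaging: ellipsoidal nuclei containing smoothed-blob chromosome
  territories with controlled pairwise overlap, plus Poisson nascent-RNA
  spots enriched in intermingling voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .layout import GenomeLayout
from .matrix import ContactMatrix

__all__ = [
    "HiCSimSpec",
    "HiCTruth",
    "ExprSimSpec",
    "ExprTruth",
    "TerritorySpec",
    "ImagingSimSpec",
    "ImagingTruth",
    "simulate_hic",
    "expected_hic_matrix",
    "simulate_expression",
    "simulate_territories",
    "random_gene_table",
]


# ---------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------


@dataclass
class HiCSimSpec:
    """Generative parameters for a synthetic genome-wide contact matrix.

    ``tad_intervals`` maps chromosome name to a list of half-open
    chromosome-local bin ranges; ``trans_preference`` is a symmetric
    positive chromosome-pair weight matrix (uniform when None);
    ``copy_number`` maps chromosome name to a contact multiplier (1.0
    diploid, 1.5 trisomic).
    """

    layout: GenomeLayout
    decay_exponent: float = 1.0
    compartment_profile: np.ndarray | None = None  # per-bin sign in {+1,-1}
    compartment_strength: float = 0.0  # kappa
    tad_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    tad_enrichment: float = 1.0  # tau
    trans_preference: np.ndarray | None = None  # pi, (n_chrom, n_chrom)
    copy_number: dict[str, float] = field(default_factory=dict)
    depth: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.compartment_strength < 1:
            raise ValueError("compartment strength must be in [0, 1) to keep rates positive")
        if self.tad_enrichment < 1:
            raise ValueError("tad_enrichment must be >= 1")
        if self.trans_preference is not None:
            pi = np.asarray(self.trans_preference, float)
            n = self.layout.n_chroms
            if pi.shape != (n, n) or not np.allclose(pi, pi.T) or (pi < 0).any():
                raise ValueError("trans_preference must be symmetric non-negative (n_chrom x n_chrom)")
        for mult in self.copy_number.values():
            if mult <= 0:
                raise ValueError("copy_number multipliers must be positive")
        for chrom, ivs in self.tad_intervals.items():
            prev_end = -1
            for s, e in sorted(ivs):
                if s < prev_end:
                    raise ValueError(f"overlapping TAD intervals on {chrom}")
                prev_end = e

    # -- per-bin vectors ----------------------------------------------
    def bin_multipliers(self) -> np.ndarray:
        m = np.ones(self.layout.n_bins)
        for chrom, mult in self.copy_number.items():
            m[self.layout.chrom_slice(chrom)] = mult
        return m

    def compartment_signs(self) -> np.ndarray:
        if self.compartment_profile is None:
            return np.ones(self.layout.n_bins)
        c = np.asarray(self.compartment_profile, float)
        if c.shape != (self.layout.n_bins,):
            raise ValueError("compartment_profile length must equal bin count")
        return c

    def tad_membership(self) -> np.ndarray:
        """Per-bin TAD id (global numbering), -1 outside any TAD."""
        member = np.full(self.layout.n_bins, -1, dtype=np.int64)
        tid = 0
        for chrom, ivs in self.tad_intervals.items():
            off = self.layout.chrom_slice(chrom).start
            for s, e in ivs:
                member[off + s : off + e] = tid
                tid += 1
        return member

    def planted_boundaries(self) -> dict[str, list[int]]:
        """Chromosome-local bin indices of planted TAD edges."""
        out = {}
        for chrom, ivs in self.tad_intervals.items():
            edges = sorted({s for s, _ in ivs} | {e for _, e in ivs})
            out[chrom] = edges
        return out


@dataclass
class HiCTruth:
    spec: HiCSimSpec
    expected_total: float

    @property
    def boundaries(self):
        return self.spec.planted_boundaries()

    @property
    def compartment_signs(self):
        return self.spec.compartment_signs()


def expected_hic_matrix(spec: HiCSimSpec) -> np.ndarray:
    """Expected (Poisson rate) full symmetric matrix for a spec.

    Cis rate at bin distance s (s=0 treated as s=1, so the diagonal is
    regular) is ``s^-decay_exponent * (1 + kappa*c_i*c_j) * tau^[same TAD]``;
    trans rate is the chromosome-pair preference.  Everything is scaled
    by the copy-number multipliers and a global factor calibrating the
    expected symmetric-matrix total to ``depth``.
    """
    spec.validate()
    lay = spec.layout
    n = lay.n_bins
    codes = lay.bin_chrom_codes()
    same_chrom = codes[:, None] == codes[None, :]

    pi = spec.trans_preference
    if pi is None:
        pi = np.ones((lay.n_chroms, lay.n_chroms))
    rate = np.asarray(pi, float)[codes[:, None], codes[None, :]].astype(float)

    # cis: power-law decay in bin distance within each chromosome
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    dist[dist == 0] = 1.0
    cis = dist ** (-spec.decay_exponent)
    c = spec.compartment_signs()
    cis = cis * (1.0 + spec.compartment_strength * np.outer(c, c))
    member = spec.tad_membership()
    same_tad = (member[:, None] == member[None, :]) & (member[:, None] >= 0)
    cis = np.where(same_tad, cis * spec.tad_enrichment, cis)
    rate = np.where(same_chrom, cis, rate)

    m = spec.bin_multipliers()
    rate *= np.outer(m, m)

    # calibrate: expected total over the full symmetric matrix = depth
    sym_total = rate.sum()  # symmetric incl. diagonal once per (i,i)
    rate *= spec.depth / sym_total
    return rate


def simulate_hic(spec: HiCSimSpec) -> tuple[ContactMatrix, HiCTruth]:
    """Sample a Poisson contact matrix from the spec's rate surface."""
    rate = expected_hic_matrix(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.layout.n_bins
    iu = np.triu_indices(n)
    upper_rates = rate[iu]
    counts = rng.poisson(upper_rates).astype(float)
    dense = np.zeros((n, n))
    dense[iu] = counts
    dense = dense + np.triu(dense, 1).T
    mat = ContactMatrix.from_dense(spec.layout, dense)
    return mat, HiCTruth(spec=spec, expected_total=spec.depth)


# ---------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------


@dataclass
class ExprSimSpec:
    """Negative-binomial expression counts with a planted dosage effect.

    The dosage factor applied to genes on ``trisomic_chrom`` is
    ``d = 1 + 0.5*(1 - compensation)``: compensation 0 gives the full
    1.5-fold expected from three copies vs. two, compensation 1 none.
    Variance follows mean + dispersion*mean^2.
    """

    genes: pd.DataFrame
    baseline_mean: np.ndarray
    dispersion: float = 0.1
    trisomic_chrom: str | None = None
    compensation: float = 0.0
    n_replicates: int = 3
    library_size: float = 1e7
    seed: int = 0

    @property
    def dosage_factor(self) -> float:
        return 1.0 + 0.5 * (1.0 - self.compensation)

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.compensation <= 1:
            raise ValueError("compensation must be in [0, 1]")
        base = np.asarray(self.baseline_mean, float)
        if base.shape != (len(self.genes),):
            raise ValueError("baseline_mean length must equal gene count")
        if (base < 0).any():
            raise ValueError("baseline means must be non-negative")


@dataclass
class ExprTruth:
    dosage_factor: float
    trisomic_chrom: str | None
    mean_wt: np.ndarray
    mean_ts: np.ndarray


def simulate_expression(spec: ExprSimSpec) -> tuple[pd.DataFrame, ExprTruth]:
    """Sample gene x sample counts for WT and trisomic replicate groups.

    Returns a count table whose columns are ``WT_1..WT_k, Ts_1..Ts_k``
    plus the ground truth (dosage factor and per-gene expected means).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = np.asarray(spec.baseline_mean, float)
    libfactor = spec.library_size / base.sum()
    d = spec.dosage_factor
    on_tri = (
        spec.genes["chrom"].to_numpy() == spec.trisomic_chrom
        if spec.trisomic_chrom is not None
        else np.zeros(len(spec.genes), bool)
    )
    mean_wt = base * libfactor
    mean_ts = mean_wt * np.where(on_tri, d, 1.0)

    def sample(mean: np.ndarray) -> np.ndarray:
        if spec.dispersion < 1e-12:
            return rng.poisson(mean)
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mean * spec.dispersion)
        return rng.poisson(lam)

    cols = {}
    for r in range(spec.n_replicates):
        cols[f"WT_{r + 1}"] = sample(mean_wt)
    for r in range(spec.n_replicates):
        cols[f"Ts_{r + 1}"] = sample(mean_ts)
    counts = pd.DataFrame(cols, index=spec.genes["gene_id"].to_numpy())
    truth = ExprTruth(d, spec.trisomic_chrom, mean_wt, mean_ts)
    return counts, truth


def random_gene_table(
    layout: GenomeLayout,
    n_genes: int,
    seed: int = 0,
    mean_exon_kb: float = 2.0,
) -> pd.DataFrame:
    """Uniformly placed genes with log-normal exon lengths, for simulations."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray(layout.chrom_lengths, float)
    probs = lengths / lengths.sum()
    which = rng.choice(layout.n_chroms, size=n_genes, p=probs)
    chroms = [layout.chrom_names[i] for i in which]
    starts = (rng.random(n_genes) * lengths[which] * 0.95).astype(np.int64)
    exon = np.maximum(
        200, (rng.lognormal(np.log(mean_exon_kb * 1000), 0.5, n_genes)).astype(np.int64)
    )
    span = np.maximum(exon, (exon * rng.uniform(1, 5, n_genes)).astype(np.int64))
    ends = np.minimum(starts + span, lengths[which].astype(np.int64))
    tab = pd.DataFrame(
        {
            "gene_id": [f"g{k:05d}" for k in range(n_genes)],
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "exon_length_bp": exon,
        }
    )
    return tab.sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------


@dataclass
class TerritorySpec:
    """One chromosome territory: label, physical target volume and placement.

    ``center`` (µm, relative to the nucleus center) fixes placement
    explicitly; if None the simulator places copies on a ring whose
    chord spacing is the spec-level ``overlap_offset``.
    """

    label: str
    target_volume: float  # µm^3
    radial_frac: float = 0.5  # 0 = nucleus center, 1 = periphery
    count: int = 1
    center: tuple[float, float, float] | None = None


@dataclass
class ImagingSimSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size: tuple[float, float, float] = (0.15, 0.15, 0.4)  # µm per axis
    nucleus_semiaxes: tuple[float, float, float] = (4.0, 4.0, 3.8)  # µm
    territories: list[TerritorySpec] = field(default_factory=list)
    overlap_offset: float = 2.0  # µm between neighbouring territory centers
    spot_rate_base: float = 0.5  # spots per µm^3 inside the nucleus
    spot_rate_intermingle: float = 1.0  # multiplier in pairwise-overlap voxels
    noise_amp: float = 0.25  # blob shape irregularity
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive per axis")
        if self.spot_rate_base < 0 or self.spot_rate_intermingle < 0:
            raise ValueError("spot rates must be non-negative")


@dataclass
class ImagingTruth:
    volumes: dict[str, float]  # µm^3 per territory mask
    overlap_volumes: dict[tuple[str, str], float]
    spot_counts: dict[str, int]
    nucleus_volume: float


def _voxel_centers(shape, voxel_size):
    axes = [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def simulate_territories(spec: ImagingSimSpec):
    """Build a synthetic nucleus image with territories and RNA spots.

    Returns ``(TerritoryImage, ImagingTruth)``.  Territory masks are
    Gaussian-smoothed noise blobs around their centers, cut at the
    weight threshold that hits the target volume exactly (top-k voxels),
    and clipped to the nucleus.  Spots are voxelwise Poisson with rate
    ``spot_rate_base`` (per µm^3) inside the nucleus, multiplied by
    ``spot_rate_intermingle`` where two or more territories overlap.
    """
    from .imaging import TerritoryImage  # local import avoids a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, vs = spec.grid_shape, spec.voxel_size
    voxel_vol = float(np.prod(vs))
    phys_center = np.array([n * v / 2 for n, v in zip(shape, vs)])
    X, Y, Z = _voxel_centers(shape, vs)
    a, b, c = spec.nucleus_semiaxes
    nucleus = (
        ((X - phys_center[0]) / a) ** 2
        + ((Y - phys_center[1]) / b) ** 2
        + ((Z - phys_center[2]) / c) ** 2
    ) <= 1.0
    nuc_vol = nucleus.sum() * voxel_vol

    # expand territory specs into individual copies with centers
    copies: list[tuple[str, TerritorySpec, np.ndarray]] = []
    pending = [
        (t, k) for t in spec.territories for k in range(t.count)
    ]
    n_copies = len(pending)
    for idx, (t, k) in enumerate(pending):
        if t.center is not None:
            center = phys_center + np.asarray(t.center)
        else:
            r = t.radial_frac * min(a, b) * 0.8
            r = max(r, 1e-6)
            # chord spacing overlap_offset on a ring of radius r
            half_angle = min(1.0, spec.overlap_offset / (2 * r))
            dtheta = 2 * np.arcsin(half_angle)
            theta = idx * dtheta
            center = phys_center + np.array(
                [r * np.cos(theta), r * np.sin(theta), 0.0]
            )
        label = t.label if t.count == 1 else f"{t.label}.{k + 1}"
        copies.append((label, t, center))

    masks: dict[str, np.ndarray] = {}
    for label, t, center in copies:
        if t.target_volume > nuc_vol:
            raise ValueError(
                f"territory {label}: target volume {t.target_volume} exceeds "
                f"nucleus volume {nuc_vol:.1f}"
            )
        target_vox = max(1, int(round(t.target_volume / voxel_vol)))
        radius = (3 * t.target_volume / (4 * np.pi)) ** (1 / 3)
        d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        weight = np.exp(-d2 / (2 * radius**2))
        if spec.noise_amp > 0:
            noise = rng.random(shape)
            sigma_vox = [radius / 2 / v for v in vs]
            noise = ndi.gaussian_filter(noise, sigma=sigma_vox)
            rng_span = noise.max() - noise.min()
            if rng_span > 0:
                noise = (noise - noise.min()) / rng_span
            weight = weight + spec.noise_amp * noise
        weight = np.where(nucleus, weight, -np.inf)
        flat = weight.ravel()
        target_vox = min(target_vox, int(nucleus.sum()))
        kth = np.argpartition(flat, -target_vox)[-target_vox:]
        mask = np.zeros(flat.shape, bool)
        mask[kth] = True
        masks[label] = mask.reshape(shape)

    labels = list(masks)
    pair_overlap = np.zeros(shape, bool)
    overlap_volumes = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            inter = masks[labels[i]] & masks[labels[j]]
            overlap_volumes[(labels[i], labels[j])] = inter.sum() * voxel_vol
            pair_overlap |= inter

    # spots: voxelwise Poisson
    rate = np.where(nucleus, spec.spot_rate_base * voxel_vol, 0.0)
    rate = np.where(pair_overlap, rate * spec.spot_rate_intermingle, rate)
    n_spots = rng.poisson(rate)
    vox_idx = np.argwhere(n_spots > 0)
    coords = []
    for iv in vox_idx:
        for _ in range(n_spots[tuple(iv)]):
            jitter = rng.random(3)
            coords.append((iv + jitter) * np.asarray(vs))
    spots = np.array(coords) if coords else np.empty((0, 3))

    image = TerritoryImage(
        voxel_size=vs,
        nucleus_mask=nucleus,
        territory_masks=masks,
        spots=spots,
    )
    spot_counts = {
        lab: int(n_spots[m].sum()) for lab, m in masks.items()
    }
    truth = ImagingTruth(
        volumes={lab: float(m.sum() * voxel_vol) for lab, m in masks.items()},
        overlap_volumes=overlap_volumes,
        spot_counts=spot_counts,
        nucleus_volume=float(nuc_vol),
    )
    return image, truth
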