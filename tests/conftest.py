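import numpy as np
import pytest

import trisomix as tx


@pytest.fixture
def toy_layout():
    """Two small chromosomes at 40-kb bins."""
    return tx.build_layout({"chrA": 400_000, "chrB": 240_000}, 40_000)


@pytest.fixture
def ten_chrom_layout():
    """Ten equal 2-Mb chromosomes at 100-kb bins (20 bins each)."""
    return tx.build_layout({f"chr{i}": 2_000_000 for i in range(1, 11)}, 100_000)


@pytest.fixture
def checkerboard_sim():
    """Two 50-Mb chromosomes at 500-kb bins with planted 5-Mb A/B blocks."""
    layout = tx.build_layout({"chr1": 50_000_000, "chr2": 50_000_000}, 500_000)
    signs = np.tile(np.repeat([1.0, -1.0], 10), 10)[: layout.n_bins]
    spec = tx.HiCSimSpec(
        layout=layout,
        compartment_profile=signs,
        compartment_strength=0.4,
        depth=2e6,
        seed=3,
    )
    return spec


@pytest.fixture
def density_for_signs():
    """Gene-density track correlated with planted compartment signs."""

    def make(layout, signs, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.where(np.asarray(signs) > 0, 10.0, 2.0) + rng.normal(0, 1, layout.n_bins)
        return tx.BinTrack(layout, vals, name="gene_density")

    return make


@pytest.fixture
def tad_sim():
    """One 10-Mb chromosome at 40-kb bins with planted TADs, tau=5."""
    rng = np.random.default_rng(5)
    n = 250
    edges = [0]
    while edges[-1] < n:
        edges.append(min(n, int(edges[-1] + rng.integers(15, 36))))
    intervals = list(zip(edges[:-1], edges[1:]))
    layout = tx.build_layout({"chr1": n * 40_000}, 40_000)
    spec = tx.HiCSimSpec(
        layout=layout,
        tad_intervals={"chr1": intervals},
        tad_enrichment=5.0,
        depth=2e6,
        seed=6,
    )
    return spec


@pytest.fixture
def expr_sim_factory():
    """Expression simulation on a 20-chromosome genome, chr1 trisomic."""

    def make(compensation=0.0, n_genes=2000, dispersion=0.1, seed=9, n_replicates=3):
        layout = tx.build_layout({f"chr{i}": 50_000_000 for i in range(1, 21)}, 1_000_000)
        genes = tx.random_gene_table(layout, n_genes, seed=7)
        rng = np.random.default_rng(8)
        spec = tx.ExprSimSpec(
            genes=genes,
            baseline_mean=rng.lognormal(3, 1, n_genes),
            dispersion=dispersion,
            trisomic_chrom="chr1",
            compensation=compensation,
            n_replicates=n_replicates,
            library_size=1e7,
            seed=seed,
        )
        return spec

    return make


def split_conditions(counts):
    wt = counts[[c for c in counts.columns if c.startswith("WT")]]
    ts = counts[[c for c in counts.columns if c.startswith("Ts")]]
    return wt, ts
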