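"""FPKM, DEG calling, shared DEG logic and dosage quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import trisomix as tx
from conftest import split_conditions


def gene_table(n, chrom="chr1", exon_bp=2000):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 5_000,
            "exon_length_bp": exon_bp,
        }
    )


class TestFPKM:
    def test_formula(self):
        genes = gene_table(2)
        counts = pd.DataFrame({"s1": [100, 10_000_000 - 100]}, index=genes["gene_id"])
        fpkm = tx.compute_fpkm(counts, genes)
        # count 100, length 2 kb, library 1e7 -> 100 / (2 * 10) = 5
        assert fpkm.loc["g0", "s1"] == pytest.approx(5.0)

    def test_zero_count_zero_fpkm(self):
        genes = gene_table(2)
        counts = pd.DataFrame({"s1": [0, 500]}, index=genes["gene_id"])
        assert tx.compute_fpkm(counts, genes).loc["g0", "s1"] == 0.0

    def test_invariant_to_depth_doubling(self):
        genes = gene_table(3)
        counts = pd.DataFrame({"s1": [10, 20, 30]}, index=genes["gene_id"])
        doubled = counts * 2
        a = tx.compute_fpkm(counts, genes)["s1"]
        b = tx.compute_fpkm(doubled, genes)["s1"]
        np.testing.assert_allclose(a, b)

    def test_zero_length_gene_errors(self):
        genes = gene_table(1)
        genes.loc[0, "exon_length_bp"] = 0
        counts = pd.DataFrame({"s1": [5]}, index=genes["gene_id"])
        with pytest.raises(ValueError):
            tx.compute_fpkm(counts, genes)


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "a,b,kept",
        [
            (0.5, 0.5, False),
            (0.5, 3.0, True),
            (1.0, 0.0, True),  # boundary: >= 1 counts as expressed
        ],
    )
    def test_filter_rule(self, a, b, kept):
        av = pd.Series({"g": a})
        bv = pd.Series({"g": b})
        assert ("g" in tx.filter_expressed(av, bv)) is kept


class TestSizeFactors:
    def test_depth_multiplier_recovered(self):
        # exactly proportional samples: factors must recover the multipliers
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=500).astype(float) + 1
        mult = np.array([1.0, 2.0, 0.5, 1.0])
        counts = pd.DataFrame(np.outer(base, mult), columns=list("abcd"))
        sf = tx.size_factors(counts)
        np.testing.assert_allclose(sf / sf.iloc[0], mult / mult[0], rtol=1e-9)

    def test_fc_invariant_to_depth_multipliers(self):
        rng = np.random.default_rng(1)
        genes = gene_table(300)
        base = rng.poisson(200, size=(300, 4)).astype(float) + 1
        wt = pd.DataFrame(base[:, :2], index=genes["gene_id"], columns=["WT_1", "WT_2"])
        ts = pd.DataFrame(base[:, 2:], index=genes["gene_id"], columns=["Ts_1", "Ts_2"])
        s1 = tx.fc_by_chromosome(ts, wt, genes)
        s2 = tx.fc_by_chromosome(ts * 3.0, wt, genes)
        np.testing.assert_allclose(s1.fc, s2.fc, rtol=1e-9)


class TestCallDegs:
    def test_identical_conditions_no_degs(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(100, size=(200, 2)).astype(float)
        a = pd.DataFrame(np.repeat(vals[:, :1], 2, axis=1), columns=["a1", "a2"])
        b = pd.DataFrame(np.repeat(vals[:, :1], 2, axis=1), columns=["b1", "b2"])
        res = tx.call_degs(a, b)
        np.testing.assert_allclose(res.table["fc"], 1.0)
        assert not res.table["deg"].any()

    def test_thresholds_both_required(self):
        # mostly-null background keeps size factors honest; planted shifts
        # of 1.25 pass the 1.2 fold-change gate, shifts of 1.15 never do
        n, n_big, n_small = 600, 100, 100
        rng = np.random.default_rng(3)
        base = rng.poisson(10_000, size=(n, 3)).astype(float)
        a = pd.DataFrame(base + rng.poisson(5, size=(n, 3)), columns=["a1", "a2", "a3"])
        fcs = np.ones(n)
        fcs[:n_big] = 1.25
        fcs[n_big : n_big + n_small] = 1.15
        b = pd.DataFrame(base * fcs[:, None], columns=["b1", "b2", "b3"])
        res = tx.call_degs(a, b)
        small = res.table.iloc[n_big : n_big + n_small]
        assert not small["deg"].any()  # FC 1.15 below the 1.2 threshold
        big = res.table.iloc[:n_big]
        assert (big["deg"] & (big["padj"] < 0.05)).sum() > 0.9 * n_big

    def test_single_replicate_errors(self):
        a = pd.DataFrame({"a1": [1, 2]})
        b = pd.DataFrame({"b1": [1, 2], "b2": [2, 3]})
        with pytest.raises(ValueError):
            tx.call_degs(a, b)

    def test_null_type_one_error_rate(self, expr_sim_factory):
        spec = expr_sim_factory(compensation=1.0)
        counts, _ = tx.simulate_expression(spec)
        wt, ts = split_conditions(counts)
        res = tx.call_degs(wt, ts)
        frac = (res.table["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert res.table["deg"].sum() <= 5


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=100), st.just(0))
    @settings(max_examples=50, derandomize=True)
    def test_matches_brute_force(self, pvals, _):
        """BH as used in the DEG caller equals O(n^2) enumeration."""
        p = np.array(pvals)
        adj = multipletests(p, method="fdr_bh")[1]
        n = len(p)
        brute = np.empty(n)
        order = np.argsort(p)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        for i in range(n):
            candidates = [
                min(1.0, p[j] * n / ranks[j]) for j in range(n) if p[j] >= p[i]
            ]
            brute[i] = min(candidates)
        np.testing.assert_allclose(adj, brute, rtol=1e-10)
        assert (adj >= p - 1e-15).all()


class TestSharedDegs:
    def _result(self, up=(), down=()):
        genes = sorted(set(up) | set(down))
        table = pd.DataFrame(
            {
                "fc": [2.0 if g in up else 0.5 for g in genes],
                "log2fc": [1.0 if g in up else -1.0 for g in genes],
                "pvalue": 0.001,
                "padj": 0.001,
                "direction": ["up" if g in up else "down" for g in genes],
                "deg": True,
            },
            index=genes,
        )
        return tx.expression.DEGResult(table)

    def test_min_support_two(self):
        res = tx.shared_degs(
            [self._result(up=["g1", "g2"]), self._result(up=["g2", "g3"]), self._result(up=["g4"])]
        )
        assert list(res["up"]) == ["g2"]

    def test_min_support_three_empty(self):
        res = tx.shared_degs(
            [self._result(up=["g1", "g2"]), self._result(up=["g2", "g3"]), self._result(up=["g4"])],
            min_support=3,
        )
        assert len(res["up"]) == 0

    def test_discordant_excluded_and_reported(self):
        res = tx.shared_degs(
            [self._result(up=["g5", "g6"]), self._result(down=["g5"]), self._result(up=["g5", "g6"])]
        )
        assert "g5" not in res["up"] and "g5" not in res["down"]
        assert list(res["discordant"]) == ["g5"]


class TestDosage:
    def test_full_dosage_recovers_planted_fold(self, expr_sim_factory):
        spec = expr_sim_factory(compensation=0.0)
        counts, truth = tx.simulate_expression(spec)
        wt, ts = split_conditions(counts)
        summary = tx.fc_by_chromosome(ts, wt, spec.genes, trisomic_chrom="chr1")
        assert truth.dosage_factor == 1.5
        assert 1.40 <= summary.trisomic_median_fc <= 1.60
        # disomic chromosomes: median FC within NB sampling error of 1
        others = summary.per_chromosome[summary.per_chromosome["chrom"] != "chr1"]
        for r in others.itertuples():
            se_median = 1.25 * np.sqrt(2 * spec.dispersion / spec.n_replicates) / np.sqrt(r.n_genes)
            assert abs(r.median_fc - 1.0) < 4 * se_median + 0.02

    def test_half_compensation(self, expr_sim_factory):
        spec = expr_sim_factory(compensation=0.5)
        counts, truth = tx.simulate_expression(spec)
        assert truth.dosage_factor == 1.25
        wt, ts = split_conditions(counts)
        summary = tx.fc_by_chromosome(ts, wt, spec.genes, trisomic_chrom="chr1")
        assert summary.trisomic_median_fc == pytest.approx(1.25, abs=0.05)
        assert summary.compensation_index == pytest.approx(0.5, abs=0.1)

    def test_self_comparison_no_trisomy(self, expr_sim_factory):
        spec = expr_sim_factory(compensation=1.0)
        counts, _ = tx.simulate_expression(spec)
        wt, _ = split_conditions(counts)
        summary = tx.fc_by_chromosome(wt, wt, spec.genes, trisomic_chrom=None)
        np.testing.assert_allclose(summary.per_chromosome["median_fc"], 1.0)
        assert np.isnan(summary.trisomic_median_fc)

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5, 1.0])
    def test_compensation_index_recovery(self, expr_sim_factory, gamma):
        spec = expr_sim_factory(compensation=gamma)
        counts, _ = tx.simulate_expression(spec)
        wt, ts = split_conditions(counts)
        summary = tx.fc_by_chromosome(ts, wt, spec.genes, trisomic_chrom="chr1")
        assert summary.compensation_index == pytest.approx(gamma, abs=0.1)

    def test_chromosome_expression_mean_fpkm(self):
        genes = pd.concat([gene_table(2, "chr1"), gene_table(2, "chr2")], ignore_index=True)
        genes["gene_id"] = [f"g{i}" for i in range(4)]
        counts = pd.DataFrame({"s1": [100, 300, 200, 400]}, index=genes["gene_id"])
        fpkm = tx.compute_fpkm(counts, genes)
        per_chrom = tx.chromosome_expression(fpkm, genes)
        assert per_chrom["chr1"] == pytest.approx(fpkm["s1"].iloc[:2].mean())
        assert per_chrom["chr2"] == pytest.approx(fpkm["s1"].iloc[2:].mean())
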