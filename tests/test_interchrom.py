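"""Inter-chromosomal proximity scores and interaction fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trisomix as tx
from trisomix.interchrom import expression_groups


def counts_from_pairs(names, pairs):
    n = len(names)
    O = np.zeros((n, n))
    for (i, j), v in pairs.items():
        O[i, j] = O[j, i] = v
    return tx.InterchromCounts(tuple(names), O)


class TestInterchromCounts:
    def test_single_trans_contact(self, toy_layout):
        mat = tx.ContactMatrix.from_triplets(toy_layout, [0], [11], [5.0])
        c = tx.interchrom_counts(mat)
        assert c.O[0, 1] == c.O[1, 0] == 5.0
        assert c.N_i.tolist() == [5.0, 5.0]
        assert c.N == 10.0

    def test_cis_only_matrix_errors_downstream(self, toy_layout):
        mat = tx.ContactMatrix.from_triplets(toy_layout, [0, 11], [1, 12], [3.0, 2.0])
        c = tx.interchrom_counts(mat)
        assert (c.O == 0).all()
        with pytest.raises(ValueError):
            tx.proximity_scores(c)

    def test_single_chromosome_errors(self):
        lay = tx.build_layout({"c": 200_000}, 40_000)
        mat = tx.ContactMatrix.from_triplets(lay, [0], [1], [1.0])
        with pytest.raises(ValueError):
            tx.interchrom_counts(mat)

    def test_uniform_preference_scales_with_bin_product(self):
        # 3 chroms with 10/20/30 bins; O_ij should track bins_i * bins_j
        lay = tx.build_layout(
            {"c1": 1_000_000, "c2": 2_000_000, "c3": 3_000_000}, 100_000
        )
        spec = tx.HiCSimSpec(layout=lay, depth=5e5, seed=20)
        expected = tx.expected_hic_matrix(spec)
        codes = lay.bin_chrom_codes()
        mat, _ = tx.simulate_hic(spec)
        obs = tx.interchrom_counts(mat).O
        # oracle: expected pair sums from the spec's rate surface
        exp = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    exp[i, j] = expected[np.ix_(codes == i, codes == j)].sum()
        for i in range(3):
            for j in range(i + 1, 3):
                sigma = np.sqrt(exp[i, j])
                assert abs(obs[i, j] - exp[i, j]) < 4 * sigma


class TestProximityScores:
    def test_symmetric_counts_give_zero_scores(self):
        c = counts_from_pairs("abc", {(0, 1): 10, (0, 2): 10, (1, 2): 10})
        res = tx.proximity_scores(c)
        assert res.R_sum == pytest.approx(2 / 3)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(res.E[off], 10.0)
        np.testing.assert_allclose(res.P[off], 0.0, atol=1e-12)

    def test_hand_evaluated_worked_example(self):
        c = counts_from_pairs("abc", {(0, 1): 20, (0, 2): 10, (1, 2): 10})
        res = tx.proximity_scores(c)
        assert res.R[0, 1] == pytest.approx(9 / 64, abs=1e-15)
        assert res.R[0, 2] == pytest.approx(3 / 32, abs=1e-15)
        assert res.R_sum == pytest.approx(0.65625, abs=1e-15)
        assert res.E[0, 1] == pytest.approx(120 / 7, abs=1e-9)
        assert res.P[0, 1] == pytest.approx(np.log2(20 / (120 / 7)), abs=1e-9)
        assert res.P[0, 2] == pytest.approx(np.log2(10 / (10 / 0.65625 * (3 / 32) * 8)), abs=1e-6)
        assert res.P[0, 2] == pytest.approx(-0.1926, abs=1e-3)

    def test_scale_invariance(self):
        c1 = counts_from_pairs("abcd", {(0, 1): 7, (0, 2): 3, (1, 2): 9, (2, 3): 4, (0, 3): 2})
        c2 = tx.InterchromCounts(c1.chrom_names, c1.O * 2)
        p1, p2 = tx.proximity_scores(c1).P, tx.proximity_scores(c2).P
        np.testing.assert_allclose(p1, p2, equal_nan=True)

    def test_zero_pair_masked_not_inf(self):
        c = counts_from_pairs("abc", {(0, 1): 10, (0, 2): 10})
        res = tx.proximity_scores(c)
        assert np.isnan(res.P[1, 2])

    @given(
        st.integers(3, 8),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_conservation_on_random_instances(self, n, seed):
        """Sum(E) = O_sum exactly and R_sum < 1 on random count matrices."""
        rng = np.random.default_rng(seed)
        O = rng.integers(1, 1000, size=(n, n)).astype(float)
        O = np.triu(O, 1)
        O = O + O.T
        res = tx.proximity_scores(tx.InterchromCounts(tuple(f"c{i}" for i in range(n)), O))
        assert res.E.sum() == pytest.approx(O.sum(), rel=1e-12)
        assert res.R_sum < 1
        assert res.R_sum == pytest.approx(1 - ((O.sum(1) / O.sum()) ** 2).sum(), rel=1e-12)


class TestICF:
    def test_plain_ratio(self, toy_layout):
        # bin 0: 70 intra (to bin 1), 30 inter (to chrB bin 10)
        mat = tx.ContactMatrix.from_triplets(toy_layout, [0, 0], [1, 10], [70.0, 30.0])
        tab = tx.icf_track(mat)
        assert tab["icf"].iloc[0] == pytest.approx(0.3)

    def test_cis_only_and_trans_only_bins(self, toy_layout):
        mat = tx.ContactMatrix.from_triplets(toy_layout, [0, 2], [1, 10], [5.0, 7.0])
        tab = tx.icf_track(mat)
        assert tab["icf"].iloc[0] == 0.0
        assert tab["icf"].iloc[2] == 1.0
        assert np.isnan(tab["icf"].iloc[3])  # no coverage

    def test_bounded_in_unit_interval(self, ten_chrom_layout):
        mat, _ = tx.simulate_hic(tx.HiCSimSpec(layout=ten_chrom_layout, depth=5e5, seed=21))
        icf = tx.icf_track(mat)["icf"].dropna()
        assert ((icf >= 0) & (icf <= 1)).all()

    def test_high_preference_pair_has_elevated_icf(self, ten_chrom_layout):
        pi = np.ones((10, 10))
        pi[0, 1] = pi[1, 0] = 6.0
        spec = tx.HiCSimSpec(layout=ten_chrom_layout, trans_preference=pi, depth=1e6, seed=22)
        mat, _ = tx.simulate_hic(spec)
        tab = tx.icf_track(mat)
        high = tab[tab["chrom"].isin(["chr1", "chr2"])]["icf"]
        assert high.mean() > tab["icf"].median()


class TestICFGroupStats:
    def test_identical_groups_p_near_one(self):
        icf = np.tile([0.1, 0.2, 0.3, 0.4], 2)
        groups = np.repeat(["x", "y"], 4)
        res = tx.icf_group_stats(icf, groups, order=["x", "y"])
        assert res.iloc[1]["p_vs_previous"] == pytest.approx(1.0)
        assert res.iloc[0]["median"] == res.iloc[1]["median"]

    def test_fpkm_cut_points(self):
        assert expression_groups(np.array([5.0, 50.0, 500.0])).tolist() == ["low", "middle", "high"]

    def test_density_coupled_preference_raises_icf_of_dense_bins(self, ten_chrom_layout):
        # chromosomes 1-5 'gene dense' with stronger mutual trans preference
        pi = np.ones((10, 10))
        pi[:5, :5] = 4.0
        spec = tx.HiCSimSpec(layout=ten_chrom_layout, trans_preference=pi, depth=1e6, seed=23)
        mat, _ = tx.simulate_hic(spec)
        tab = tx.icf_track(mat)
        dense_group = np.where(
            tab["chrom"].isin([f"chr{i}" for i in range(1, 6)]), "dense", "sparse"
        )
        res = tx.icf_group_stats(tab["icf"].to_numpy(), dense_group, order=["sparse", "dense"])
        assert res.set_index("group").loc["dense", "median"] > res.set_index("group").loc["sparse", "median"]
        assert res.iloc[1]["p_vs_previous"] < 0.01

    def test_small_group_flagged(self):
        res = tx.icf_group_stats(np.array([0.1, 0.2, 0.3]), np.array(["a", "a", "b"]), order=["a", "b"])
        assert res.set_index("group").loc["b", "flagged"]


class TestDensityAssociation:
    def test_positive_when_preference_tracks_density(self, ten_chrom_layout):
        dens = {f"chr{i}": float(i) for i in range(1, 11)}
        d = np.array([dens[c] for c in ten_chrom_layout.chrom_names])
        pi = np.outer(d, d) / d.mean() ** 2
        spec = tx.HiCSimSpec(layout=ten_chrom_layout, trans_preference=pi, depth=2e6, seed=24)
        mat, _ = tx.simulate_hic(spec)
        res = tx.density_association(
            tx.proximity_scores(tx.interchrom_counts(mat)), dens, focal="chr5"
        )
        assert res["pearson"] > 0
        assert res["spearman"] > 0

    def test_constant_density_flagged(self):
        c = counts_from_pairs("abcd", {(0, 1): 7, (0, 2): 3, (1, 2): 9, (0, 3): 5, (1, 3): 2, (2, 3): 8})
        res = tx.density_association(tx.proximity_scores(c), {k: 1.0 for k in "abcd"}, focal="a")
        assert np.isnan(res["pearson"])

    def test_too_few_partners_errors(self):
        c = counts_from_pairs("abc", {(0, 1): 5, (0, 2): 5, (1, 2): 5})
        with pytest.raises(ValueError):
            tx.density_association(tx.proximity_scores(c), {"a": 1.0, "b": 2.0, "c": 3.0}, focal="a")

    def test_invariant_to_chromosome_permutation(self):
        pairs = {(0, 1): 7, (0, 2): 3, (1, 2): 9, (0, 3): 5, (1, 3): 2, (2, 3): 8}
        c = counts_from_pairs("abcd", pairs)
        dens = {"a": 1.0, "b": 5.0, "c": 2.0, "d": 9.0}
        r1 = tx.density_association(tx.proximity_scores(c), dens, focal="a")
        # permute order b,d,c after a
        perm = [0, 1, 3, 2]
        O2 = c.O[np.ix_(perm, perm)]
        c2 = tx.InterchromCounts(("a", "b", "d", "c"), O2)
        r2 = tx.density_association(tx.proximity_scores(c2), dens, focal="a")
        assert r1["pearson"] == pytest.approx(r2["pearson"])
        assert r1["spearman"] == pytest.approx(r2["spearman"])


class TestCopyNumberRobustness:
    def test_proximity_absorbs_trisomic_marginal_inflation(self, ten_chrom_layout):
        rng = np.random.default_rng(25)
        pi = np.ones((10, 10)) + np.abs(rng.normal(0, 0.3, (10, 10)))
        pi = (pi + pi.T) / 2
        wt_spec = tx.HiCSimSpec(layout=ten_chrom_layout, trans_preference=pi, depth=2e6, seed=26)
        ts_spec = tx.HiCSimSpec(
            layout=ten_chrom_layout, trans_preference=pi, copy_number={"chr1": 1.5}, depth=2e6, seed=27
        )
        p_wt = tx.proximity_scores(tx.interchrom_counts(tx.simulate_hic(wt_spec)[0])).P
        p_ts = tx.proximity_scores(tx.interchrom_counts(tx.simulate_hic(ts_spec)[0])).P
        iu = np.triu_indices(10, 1)
        ok = np.isfinite(p_wt[iu]) & np.isfinite(p_ts[iu])
        r = np.corrcoef(p_wt[iu][ok], p_ts[iu][ok])[0, 1]
        assert r > 0.9
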