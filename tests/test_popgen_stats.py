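import numpy as np
import pytest

from conftest import disjoint_pools, stack_matrices
from cryptohyb.genodata import MISSING, GenotypeMatrix
from cryptohyb.popgen_stats import (
    allelic_richness,
    bonferroni,
    hwe_test,
    ld_test,
    locus_summaries,
    null_allele_scan,
    pairwise_fst,
    sex_biased_dispersal_test,
    wc_theta,
)
from cryptohyb.synthetic_data import (
    SimulationConfig,
    draw_allele_frequencies,
    simulate_parental_genotypes,
)
from oracles import wc_theta_literal


def _random_matrix(rng, n=12, L=4, amax=6, miss=0.1):
    alleles = rng.integers(1, amax, size=(n, L, 2))
    m = rng.random((n, L)) < miss
    alleles[m] = MISSING
    return GenotypeMatrix([f"i{k}" for k in range(n)], [f"L{k}" for k in range(L)], alleles)


class TestLocusSummaries:
    def test_monomorphic_locus(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["L1"], np.full((3, 1, 2), 9))
        row = locus_summaries(gm, ["g1", "g1", "g1"]).iloc[0]
        assert row.Na == 1 and row.Ho == 0 and row.He == 0
        assert np.isnan(row.Fis)

    def test_hand_computed_four_individual_example(self):
        # group g: genotypes (1,1), (1,2), (2,2), (1,2); n=4
        # p1 = 0.5; Ho = 0.5; He = 8/7 * (1 - 0.5) = 4/7
        alleles = np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
        gm = GenotypeMatrix(list("abcd"), ["L1"], alleles)
        row = locus_summaries(gm, ["g"] * 4).iloc[0]
        assert row.Na == 2
        assert row.Ho == pytest.approx(0.5)
        assert row.He == pytest.approx(8 / 7 * 0.5)
        # Weir-Cockerham single-sample f, from the r=1 components by hand:
        # per allele (p=q=0.5, h=0.5): b = 4/3*(0.25 - 7/16*0.5) = 1/24, c = 0.25
        # f = 1 - (2*0.25) / (2*(1/24 + 0.25)) = 1 - 0.5/(7/12) = 1/7
        assert row.Fis == pytest.approx(1 / 7)

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        gm = _random_matrix(rng)
        labels = ["g1"] * 6 + ["g2"] * 6
        base = locus_summaries(gm, labels)
        remap = {a: a * 13 + 5 for a in range(1, 30)}
        remap[MISSING] = MISSING
        relabeled = np.vectorize(remap.get)(gm.alleles)
        gm2 = GenotypeMatrix(gm.individual_ids, gm.locus_names, relabeled)
        other = locus_summaries(gm2, labels)
        for col in ("Na", "Ho", "He", "Fis", "Fst"):
            np.testing.assert_allclose(
                base[col].to_numpy(dtype=float), other[col].to_numpy(dtype=float),
                atol=1e-12, equal_nan=True,
            )


class TestWcTheta:
    def test_identical_pools_give_near_zero_theta(self):
        rng = np.random.default_rng(1)
        cfg = SimulationConfig(n_loci=12, seed=1)
        codes, freqs, anc = draw_allele_frequencies(cfg, rng)
        g1 = simulate_parental_genotypes(codes, anc, 500, rng, id_prefix="x")
        g2 = simulate_parental_genotypes(codes, anc, 500, rng, id_prefix="y")
        gm = stack_matrices(g1, g2)
        res = wc_theta(gm, ["a"] * 500 + ["b"] * 500, n_boot=200, seed=0)
        assert abs(res.theta) < 0.01
        assert res.ci95[0] <= res.theta <= res.ci95[1]

    def test_disjointly_fixed_pools_give_theta_one(self):
        gA, gB = disjoint_pools(8, 4)
        gm = stack_matrices(gA, gB)
        res = wc_theta(gm, ["A"] * 8 + ["B"] * 8, n_boot=0)
        assert res.theta == pytest.approx(1.0)

    def test_matches_literal_formula_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            gm = _random_matrix(rng, n=rng.integers(6, 16), L=rng.integers(1, 5))
            labels = rng.choice(["p", "q"], size=gm.n_individuals)
            while len(set(labels[: gm.n_individuals])) < 2 or min(
                (labels == "p").sum(), (labels == "q").sum()
            ) < 2:
                labels = rng.choice(["p", "q"], size=gm.n_individuals)
            try:
                expect = wc_theta_literal(gm, labels)
            except ZeroDivisionError:
                continue
            got = wc_theta(gm, labels, n_boot=0).theta
            assert got == pytest.approx(expect, abs=1e-12)

    def test_theta_is_ratio_of_summed_components(self):
        rng = np.random.default_rng(3)
        gm = _random_matrix(rng, n=20, L=6)
        labels = ["a"] * 10 + ["b"] * 10
        from cryptohyb.popgen_stats import wc_components

        comp = wc_components(gm, labels)
        res = wc_theta(gm, labels, n_boot=0)
        assert res.theta == pytest.approx(
            comp["a"].sum() / (comp["a"] + comp["b"] + comp["c"]).sum()
        )


class TestPairwiseFst:
    def test_duplicated_group_not_significant(self):
        rng = np.random.default_rng(4)
        half = _random_matrix(rng, n=20, L=5, miss=0.0)
        gm = GenotypeMatrix(
            half.individual_ids + [f"dup_{i}" for i in half.individual_ids],
            half.locus_names,
            np.concatenate([half.alleles, half.alleles]),
        )
        perm = rng.permutation(40)
        labels = np.array(["u"] * 20 + ["v"] * 20)[perm]
        gm = GenotypeMatrix(
            [gm.individual_ids[i] for i in perm], gm.locus_names, gm.alleles[perm]
        )
        df = pairwise_fst(gm, labels, n_perm=99, seed=0)
        assert df.loc[0, "p_value"] > 0.05
        assert abs(df.loc[0, "theta"]) < 0.05

    def test_disjoint_groups_minimal_p(self):
        gA, gB = disjoint_pools(10, 3)
        gm = stack_matrices(gA, gB)
        df = pairwise_fst(gm, ["A"] * 10 + ["B"] * 10, n_perm=99, seed=0)
        # the observed partition maximizes G; only a permutation recovering it
        # (or its complement) can tie, so p is at the includes-observed floor
        # up to that rare event
        assert df.loc[0, "p_value"] <= 2 / 100

    def test_g_statistic_hand_value(self):
        from cryptohyb.popgen_stats import _g_stat_alleles

        # 2x2 allele counts: group0 has 6 copies of allele1, 2 of allele2;
        # group1 has 2 and 6.  G = 2*sum O ln(O/E), E = 4 everywhere.
        alleles = np.array(
            [[[1, 1]], [[1, 1]], [[1, 2]], [[1, 2]], [[2, 1]], [[1, 2]], [[2, 2]], [[2, 2]]]
        )
        gm = GenotypeMatrix([f"i{k}" for k in range(8)], ["L1"], alleles)
        sub_labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        got = _g_stat_alleles(gm, sub_labels, gm.alleles)
        expect = 2 * (2 * 6 * np.log(6 / 4) + 2 * 2 * np.log(2 / 4))
        assert got == pytest.approx(expect, abs=1e-12)


class TestHwe:
    def test_extreme_heterozygote_deficit_detected(self):
        rng = np.random.default_rng(5)
        # 50 individuals, all homozygous, alleles 1 and 2 at p = q = 0.5
        hom = np.array([1] * 25 + [2] * 25)[rng.permutation(50)]
        alleles = np.stack([hom, hom], axis=1)[:, None, :]
        gm = GenotypeMatrix([f"i{k}" for k in range(50)], ["L1"], alleles)
        df = hwe_test(gm, ["g"] * 50, n_perm=9999, seed=0)
        assert df.loc[0, "p_value"] < 0.001
        assert df.loc[0, "fis"] > 0.9

    def test_monomorphic_locus_is_na(self):
        gm = GenotypeMatrix(list("abcdef"), ["L1"], np.full((6, 1, 2), 3))
        df = hwe_test(gm, ["g"] * 6, n_perm=99, seed=0)
        assert np.isnan(df.loc[0, "p_value"])

    def test_hw_simulated_locus_not_flagged(self):
        rng = np.random.default_rng(6)
        p = np.array([0.4, 0.3, 0.2, 0.1])
        gm = simulate_parental_genotypes([np.arange(1, 5)], [p], 200, rng)
        df = hwe_test(gm, ["g"] * 200, n_perm=999, seed=1)
        assert df.loc[0, "p_value"] > 0.01


class TestLd:
    def test_duplicated_locus_minimal_p(self):
        rng = np.random.default_rng(7)
        col = rng.integers(1, 4, size=(40, 1, 2))
        alleles = np.concatenate([col, col], axis=1)
        gm = GenotypeMatrix([f"i{k}" for k in range(40)], ["L1", "L2"], alleles)
        df = ld_test(gm, ["g"] * 40, n_perm=99, seed=0)
        assert df.loc[0, "p_value"] == pytest.approx(1 / 100)

    def test_independent_loci_not_extreme(self):
        rng = np.random.default_rng(8)
        gm = _random_matrix(rng, n=60, L=4, amax=5, miss=0.0)
        df = ld_test(gm, ["g"] * 60, n_perm=199, seed=1)
        assert (df["p_value"] > 0.005).all()
        assert 0.15 < df["p_value"].mean() < 0.95


class TestNullAlleles:
    def test_complete_homozygosity_estimates_one(self):
        rng = np.random.default_rng(9)
        hom = rng.integers(1, 3, size=40)
        alleles = np.stack([hom, hom], axis=1)[:, None, :]
        gm = GenotypeMatrix([f"i{k}" for k in range(40)], ["L1"], alleles)
        df = null_allele_scan(gm, ["g"] * 40)
        assert df.loc[0, "null_freq"] == pytest.approx(1.0)
        assert df.loc[0, "p_value"] < 0.001

    def test_hw_locus_estimates_near_zero(self):
        rng = np.random.default_rng(10)
        p = np.array([0.5, 0.5])
        gm = simulate_parental_genotypes([np.array([1, 2])], [p], 2000, rng)
        df = null_allele_scan(gm, ["g"] * 2000)
        assert abs(df.loc[0, "null_freq"]) < 0.05
        assert df.loc[0, "p_value"] > 0.05

    def test_brookfield_option(self):
        rng = np.random.default_rng(11)
        gm = _random_matrix(rng, n=30, L=2, miss=0.0)
        a = null_allele_scan(gm, ["g"] * 30, estimator="chakraborty")
        b = null_allele_scan(gm, ["g"] * 30, estimator="brookfield")
        assert not np.allclose(
            a["null_freq"].to_numpy(dtype=float), b["null_freq"].to_numpy(dtype=float)
        )
        with pytest.raises(ValueError):
            null_allele_scan(gm, ["g"] * 30, estimator="bogus")


class TestSexBiasedDispersal:
    def test_identical_sexes_give_zero_statistic(self):
        rng = np.random.default_rng(12)
        half = _random_matrix(rng, n=30, L=5, miss=0.0)
        gm = GenotypeMatrix(
            half.individual_ids + [f"m{i}" for i in range(30)],
            half.locus_names,
            np.concatenate([half.alleles, half.alleles]),
        )
        sex = ["F"] * 30 + ["M"] * 30
        site = (["s1"] * 15 + ["s2"] * 15) * 2
        res = sex_biased_dispersal_test(gm, sex, site, n_rand=49, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_no_structure_not_significant(self):
        rng = np.random.default_rng(13)
        cfg = SimulationConfig(n_loci=8, seed=13)
        codes, freqs, anc = draw_allele_frequencies(cfg, rng)
        gm = simulate_parental_genotypes(codes, anc, 120, rng)
        sex = rng.choice(["F", "M"], size=120)
        site = rng.choice(["s1", "s2", "s3"], size=120)
        res = sex_biased_dispersal_test(gm, sex, site, n_rand=199, seed=1)
        assert res.p_value > 0.01
        assert res.n_permutations > 0

    def test_requires_both_sexes_in_two_sites(self):
        gA, _ = disjoint_pools(6, 3)
        with pytest.raises(ValueError):
            sex_biased_dispersal_test(gA, ["F"] * 6, ["s1"] * 3 + ["s2"] * 3, n_rand=9)


def test_bonferroni_caps_at_one():
    out = bonferroni(np.array([0.5, 0.001, 0.04]))
    assert out.tolist() == [1.0, 0.003, 0.12]


def test_allelic_richness_bounded_by_na():
    rng = np.random.default_rng(14)
    gm = _random_matrix(rng, n=30, L=4, miss=0.05)
    labels = ["a"] * 15 + ["b"] * 15
    rich = allelic_richness(gm, labels, g=5)
    summ = locus_summaries(gm, labels)
    merged = rich.merge(summ, on=["locus", "group"])
    ok = merged.dropna(subset=["richness"])
    assert (ok["richness"] <= ok["Na"] + 1e-9).all()
    assert (ok["richness"] >= 1 - 1e-9).all()
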