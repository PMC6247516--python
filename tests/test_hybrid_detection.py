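import numpy as np
import pytest

from conftest import disjoint_pools
from cryptohyb.admixture import ConsensusAssignment, McmcConfig
from cryptohyb.hybrid_detection import (
    HybridSimConfig,
    ThresholdPair,
    calibrate_thresholds,
    classify,
    misclassification_class_counts,
    misclassification_study,
    select_reference_parents,
    simulate_hybrid_classes,
)


def _consensus(q, ci_lo=None, ids=None) -> ConsensusAssignment:
    q = np.asarray(q, dtype=float)
    ci_lo = q - 0.1 if ci_lo is None else np.asarray(ci_lo, dtype=float)
    return ConsensusAssignment(
        q=q,
        ci90_lower=ci_lo,
        ci90_upper=np.minimum(q + 0.1, 1.0),
        n_runs=1,
        label_permutations=[(0, 1)],
        individual_ids=ids or [f"i{k}" for k in range(q.shape[0])],
    )


class TestSelectReferenceParents:
    def test_single_highest_per_cluster(self):
        cons = _consensus([[0.99, 0.01], [0.8, 0.2], [0.1, 0.9], [0.3, 0.7]])
        a, b = select_reference_parents(cons, n=1)
        assert a == ["i0"] and b == ["i2"]

    def test_ties_broken_by_id_order(self):
        cons = _consensus(
            [[1.0, 0.0]] * 5 + [[0.0, 1.0]],
            ids=["e", "c", "a", "d", "b", "z"],
        )
        a, _ = select_reference_parents(cons, n=3)
        assert a == ["a", "b", "c"]

    def test_small_cluster_taken_whole_with_warning(self):
        cons = _consensus([[0.9, 0.1], [0.2, 0.8], [0.1, 0.9]])
        with pytest.warns(UserWarning, match="only 1"):
            a, b = select_reference_parents(cons, n=2)
        assert a == ["i0"] and set(b) == {"i1", "i2"}


class TestSimulateHybridClasses:
    def test_f1_from_fixed_pools_is_heterozygous_everywhere(self):
        gA, gB = disjoint_pools(5, 4)
        cfg = HybridSimConfig(class_counts={"F1": 20}, seed=0)
        sim, labels = simulate_hybrid_classes(gA, gB, cfg)
        assert labels == ["F1"] * 20
        assert (np.sort(sim.alleles, axis=2) == [11, 23]).all()

    def test_backcross_allele_fraction_three_quarters(self):
        gA, gB = disjoint_pools(5, 1)
        cfg = HybridSimConfig(class_counts={"BC_A": 10000}, seed=1)
        sim, _ = simulate_hybrid_classes(gA, gB, cfg)
        frac_a = (sim.alleles == 11).mean()
        # 10000 simulants x 2 alleles: binomial(20000, 0.75), ~4 sd tolerance
        assert frac_a == pytest.approx(0.75, abs=0.013)

    def test_all_zero_counts_rejected(self):
        gA, gB = disjoint_pools(3, 2)
        with pytest.raises(ValueError, match="nothing to simulate"):
            simulate_hybrid_classes(gA, gB, HybridSimConfig(class_counts={}, seed=0))

    def test_mismatched_loci_rejected(self):
        gA, gB = disjoint_pools(3, 2)
        gB2 = gB.subset(loci=gB.locus_names[:1])
        with pytest.raises(ValueError, match="same loci"):
            simulate_hybrid_classes(gA, gB2, HybridSimConfig(seed=0))

    def test_parental_classes_draw_from_own_pool_only(self):
        gA, gB = disjoint_pools(4, 3)
        cfg = HybridSimConfig(class_counts={"parentalA": 50, "parentalB": 50}, seed=2)
        sim, labels = simulate_hybrid_classes(gA, gB, cfg)
        lab = np.asarray(labels)
        assert (sim.alleles[lab == "parentalA"] == 11).all()
        assert (sim.alleles[lab == "parentalB"] == 23).all()


class TestThresholds:
    def test_threshold_is_minimum_parental_q(self):
        q = [[0.99, 0.01], [0.95, 0.05], [0.03, 0.97], [0.2, 0.8]]
        labels = ["parentalA", "parentalA", "parentalB", "parentalB"]
        tp = calibrate_thresholds(_consensus(q), labels)
        assert tp.TP1 == pytest.approx(0.95)
        assert tp.TP2 == pytest.approx(0.8)

    def test_thresholds_non_increasing_with_more_parents(self):
        rng = np.random.default_rng(3)
        qs = 0.7 + 0.3 * rng.random(40)
        prev = None
        for m in (5, 10, 20, 40):
            q = np.column_stack([qs[:m], 1 - qs[:m]])
            q = np.vstack([q, [[0.1, 0.9]]])
            labels = ["parentalA"] * m + ["parentalB"]
            tp = calibrate_thresholds(_consensus(q), labels)
            if prev is not None:
                assert tp.TP1 <= prev + 1e-12
            prev = tp.TP1

    def test_requires_both_parental_classes(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(_consensus([[0.9, 0.1]]), ["F1"])


class TestClassify:
    TP = ThresholdPair(TP1=0.90, TP2=0.76)

    def test_conservative_parent_relaxed_hybrid(self):
        cons = _consensus([[0.95, 0.05]], ci_lo=[[0.80, 0.0]])
        t = classify(cons, self.TP).table
        assert t.loc[0, "conservative"] == "parent_1"
        assert t.loc[0, "relaxed"] == "hybrid"

    def test_clear_parent_under_both(self):
        cons = _consensus([[1.0, 0.0]], ci_lo=[[1.0, 0.0]])
        t = classify(cons, self.TP).table
        assert t.loc[0, "conservative"] == "parent_1"
        assert t.loc[0, "relaxed"] == "parent_1"

    def test_even_admixture_hybrid_under_both(self):
        cons = _consensus([[0.5, 0.5]], ci_lo=[[0.4, 0.4]])
        t = classify(cons, self.TP).table
        assert t.loc[0, "conservative"] == "hybrid"
        assert t.loc[0, "relaxed"] == "hybrid"

    def test_conservative_hybrids_subset_of_relaxed(self):
        rng = np.random.default_rng(4)
        q1 = rng.random(200)
        q = np.column_stack([q1, 1 - q1])
        ci = np.clip(q - rng.random((200, 2)) * 0.2, 0, 1)
        calls = classify(_consensus(q, ci_lo=ci), self.TP)
        assert set(calls.conservative_hybrids) <= set(calls.relaxed_hybrids)

    def test_cluster_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        q1 = rng.random(50)
        q = np.column_stack([q1, 1 - q1])
        ci = np.clip(q - 0.15, 0, 1)
        a = classify(_consensus(q, ci_lo=ci), self.TP)
        swapped = ThresholdPair(TP1=self.TP.TP2, TP2=self.TP.TP1)
        b = classify(_consensus(q[:, ::-1], ci_lo=ci[:, ::-1]), swapped)
        assert a.relaxed_hybrids == b.relaxed_hybrids
        assert a.conservative_hybrids == b.conservative_hybrids


def test_misclassification_zero_for_disjoint_pools():
    gA, gB = disjoint_pools(20, 5)
    cfg = HybridSimConfig(
        class_counts={"parentalA": 30, "parentalB": 30, "F1": 2, "BC_A": 2, "BC_B": 2},
        seed=0,
    )
    mcmc = McmcConfig(K=2, burn_in=300, length=1200, thin=4)
    df = misclassification_study(
        gA, gB, ThresholdPair(0.9, 0.9), cfg=cfg, mcmc=mcmc, n_replicates=2, seed=1
    )
    assert df.attrs["overall_rate_conservative"] == 0.0
    assert df.attrs["overall_rate_relaxed"] == 0.0
    assert (df["n_parental"] == 60).all()


def test_study_class_mix_preset():
    counts = misclassification_class_counts()
    assert counts == {
        "parentalA": 300, "parentalB": 300, "F1": 10, "F2": 0, "BC_A": 15, "BC_B": 15
    }
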