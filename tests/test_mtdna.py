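import numpy as np
import pytest

from cryptohyb.genodata import AlignedSequences
from cryptohyb.mtdna import (
    cytonuclear_discordance,
    haplogroup_partition,
    raw_distance,
)
from oracles import raw_distance_bruteforce


class TestRawDistance:
    def test_identical_and_single_difference(self):
        dm = raw_distance(AlignedSequences(["a", "b", "c"], ["ACGT", "ACGT", "ACGA"]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx(0.25)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.allclose(dm.values, dm.values.T)

    def test_pairwise_deletion_of_gaps(self):
        dm = raw_distance(AlignedSequences(["a", "b"], ["AC-T", "ACGT"]))
        assert dm.values[0, 1] == 0.0
        assert dm.pairwise_sites_used[0, 1] == 3

    def test_n_treated_as_missing(self):
        dm = raw_distance(AlignedSequences(["a", "b"], ["ANGT", "ACGA"]))
        # comparable sites: A, G, T vs A, G, A -> 1 difference of 3
        assert dm.values[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="no comparable sites"):
            dm = raw_distance(AlignedSequences(["a", "b"], ["A---", "-CGT"]))
        assert np.isnan(dm.values[0, 1])

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(1)
        chars = np.array(list("ACGTN-"))
        seqs = ["".join(rng.choice(chars, p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04], size=60))
                for _ in range(12)]
        aln = AlignedSequences([f"s{i}" for i in range(12)], seqs)
        got = raw_distance(aln).values
        expect = raw_distance_bruteforce(aln)
        np.testing.assert_array_equal(got, expect)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(6)]
        ids = [f"s{i}" for i in range(6)]
        a = raw_distance(AlignedSequences(ids, seqs))
        perm = [3, 1, 5, 0, 2, 4]
        b = raw_distance(AlignedSequences([ids[i] for i in perm], [seqs[i] for i in perm]))
        back = np.argsort(perm)
        np.testing.assert_allclose(b.values[np.ix_(back, back)], a.values)


class TestHaplogroupPartition:
    def test_identical_sequences_one_group(self):
        dm = raw_distance(AlignedSequences(["a", "b", "c"], ["ACGT"] * 3))
        part = haplogroup_partition(dm, cutoff=0.02)
        assert set(part.labels.values()) == {0}
        assert part.within_means[0] == 0.0

    def test_two_clouds_separate_at_default_cutoff(self, default_dataset):
        _, coi, _, truth = default_dataset
        part = haplogroup_partition(raw_distance(coi), cutoff=0.02)
        groups = np.array([part.labels[i] for i in coi.ids])
        mt = truth.table.loc[coi.ids, "mt_haplogroup"].to_numpy()
        assert len(set(groups.tolist())) == 2
        # perfect agreement with the generating haplogroups (up to naming)
        same = (groups == groups[0]) == (mt == mt[0])
        assert same.all()
        assert part.between_mean > 0.04
        assert part.max_within < part.min_between

    def test_lowering_cutoff_never_merges(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(8)]
        dm = raw_distance(AlignedSequences([f"s{i}" for i in range(8)], seqs))
        prev = None
        for cutoff in (0.9, 0.6, 0.3, 0.1, 0.01):
            part = haplogroup_partition(dm, cutoff=cutoff)
            n_groups = len(set(part.labels.values()))
            if prev is not None:
                assert n_groups >= prev
            prev = n_groups

    def test_cutoff_domain(self):
        dm = raw_distance(AlignedSequences(["a", "b"], ["ACGT", "ACGT"]))
        with pytest.raises(ValueError):
            haplogroup_partition(dm, cutoff=1.5)


class TestDiscordance:
    def test_fully_concordant(self):
        nuc = {f"i{k}": "A" if k < 3 else "B" for k in range(6)}
        tab = cytonuclear_discordance(nuc, nuc)
        assert tab.table.values.trace() == 6
        assert not tab.asymmetric
        assert all(v == 0 for v in tab.proportions.values())

    def test_study_pattern_six_of_thirtyeight(self):
        nuc = {}
        mt = {}
        for k in range(38):
            nuc[f"a{k}"] = "A"
            mt[f"a{k}"] = "B" if k < 6 else "A"
        for k in range(42):
            nuc[f"b{k}"] = "B"
            mt[f"b{k}"] = "B"
        tab = cytonuclear_discordance(nuc, mt)
        assert tab.proportions[("A", "B")] == pytest.approx(6 / 38)
        assert tab.proportions[("B", "A")] == 0.0
        assert tab.asymmetric
        # marginals equal the label counts
        assert tab.table.sum(axis=1).to_dict() == {"A": 38, "B": 42}
        assert int(tab.table.values.sum()) == 80

    def test_disjoint_ids_rejected(self):
        with pytest.raises(ValueError):
            cytonuclear_discordance({"x": "A"}, {"y": "B"})
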