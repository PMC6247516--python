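import numpy as np
import pytest

from conftest import disjoint_pools, stack_matrices
from cryptohyb.admixture import (
    ConsensusAssignment,
    McmcConfig,
    RunResult,
    align_runs,
    assign_clusters,
    desk_config,
    evanno_deltaK,
    run_admixture,
)
from cryptohyb.genodata import MISSING, GenotypeMatrix

FAST = dict(burn_in=300, length=1200, thin=4)


def test_k1_gives_unit_ancestry():
    gA, _ = disjoint_pools(6, 3)
    run = run_admixture(gA, McmcConfig(K=1, seed=0, **FAST))
    assert np.allclose(run.q_mean, 1.0)
    assert np.allclose(run.q_mean.sum(axis=1), 1.0, atol=1e-9)


def test_disjoint_populations_fully_resolved():
    """Populations fixed for disjoint alleles: the posterior must sit on the
    generating labels (exact posterior concentrates there)."""
    gA, gB = disjoint_pools(10, 5)
    gm = stack_matrices(gA, gB)
    run = run_admixture(gm, McmcConfig(K=2, seed=1, burn_in=500, length=3000, thin=4))
    k_of_A = int(run.q_mean[:10].mean(axis=0).argmax())
    indicator = np.zeros((20, 2))
    indicator[:10, k_of_A] = 1
    indicator[10:, 1 - k_of_A] = 1
    assert np.abs(run.q_mean - indicator).max() < 0.02
    lo, hi = run.q_ci90
    assert (lo <= run.q_mean + 1e-12).all() and (run.q_mean <= hi + 1e-12).all()


def test_k_exceeding_n_rejected():
    gA, _ = disjoint_pools(3, 2)
    with pytest.raises(ValueError, match="exceeds"):
        run_admixture(gA, McmcConfig(K=5, seed=0, **FAST))


def test_all_missing_individual_warns_and_gets_prior():
    alleles = np.full((6, 4, 2), 7, dtype=np.int64)
    alleles[5] = MISSING
    gm = GenotypeMatrix([f"i{k}" for k in range(6)], list("ABCD"), alleles)
    with pytest.warns(UserWarning, match="no amplified loci"):
        run = run_admixture(gm, McmcConfig(K=2, seed=3, **FAST))
    assert run.q_mean.shape == (6, 2)


def test_no_data_posterior_matches_prior():
    """With every genotype missing the ancestry posterior is its prior,
    whose mean is 1/K for each cluster."""
    alleles = np.full((8, 3, 2), MISSING, dtype=np.int64)
    gm = GenotypeMatrix([f"i{k}" for k in range(8)], list("XYZ"), alleles)
    with pytest.warns(UserWarning):
        run = run_admixture(gm, McmcConfig(K=2, seed=4, burn_in=500, length=4000, thin=4))
    assert np.abs(run.q_mean - 0.5).max() < 0.06


def test_lnpd_matches_trace_formula():
    gA, gB = disjoint_pools(5, 3)
    run = run_admixture(stack_matrices(gA, gB), McmcConfig(K=2, seed=5, **FAST))
    t = run.loglik_trace
    assert run.lnPD == pytest.approx(t.mean() - t.var(ddof=0) / 2, abs=1e-9)


def _mk_run(q, ids=None) -> RunResult:
    q = np.asarray(q, dtype=float)
    return RunResult(
        q_mean=q,
        q_ci90=(q - 0.05, q + 0.05),
        P_mean=np.zeros((q.shape[1], 1, 1)),
        alpha_trace=np.zeros(1),
        loglik_trace=np.zeros(1),
        lnPD=0.0,
        individual_ids=ids or [f"i{k}" for k in range(q.shape[0])],
    )


def test_align_runs_label_switching_invariance():
    q = np.array([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
    consensus = align_runs([_mk_run(q), _mk_run(q[:, ::-1])])
    assert np.allclose(consensus.q, q)
    assert consensus.label_permutations == [(0, 1), (1, 0)]


def test_align_single_run_is_identity():
    q = np.array([[0.6, 0.4], [0.3, 0.7]])
    consensus = align_runs([_mk_run(q)])
    assert np.allclose(consensus.q, q)
    assert np.allclose(consensus.ci90_lower, q - 0.05)


def test_align_runs_averaging_matches_bruteforce_k3():
    import itertools

    rng = np.random.default_rng(7)
    base = rng.dirichlet(np.ones(3), size=6)
    runs = []
    perms_applied = [(0, 1, 2), (2, 0, 1), (1, 2, 0)]
    for p in perms_applied:
        noisy = np.clip(base[:, p] + rng.normal(0, 0.01, base.shape), 1e-6, None)
        runs.append(_mk_run(noisy / noisy.sum(axis=1, keepdims=True)))
    consensus = align_runs(runs)
    # brute force: best permutation per run over all 3! options, then average
    aligned = [runs[0].q_mean]
    for r in runs[1:]:
        best = min(
            itertools.permutations(range(3)),
            key=lambda p: np.abs(runs[0].q_mean - r.q_mean[:, p]).sum(),
        )
        aligned.append(r.q_mean[:, best])
    assert np.allclose(consensus.q, np.mean(aligned, axis=0))


def test_align_runs_rejects_mismatched_k():
    with pytest.raises(ValueError):
        align_runs([_mk_run(np.full((2, 2), 0.5)), _mk_run(np.full((2, 3), 1 / 3))])


def test_evanno_zero_for_linear_lnpd():
    table = evanno_deltaK({1: [-10.0, -10.1], 2: [-8.0, -8.1], 3: [-6.0, -6.1]})
    assert table.table["deltaK"].iloc[1] == pytest.approx(0.0, abs=1e-9)


def test_evanno_hand_example():
    # means (-100, -50, -49, -48.5), sd 1 at each K:
    # deltaK(2) = |(-49) - 2(-50) + (-100)| / 1 = 49
    lnpd = {
        1: [-101.0, -99.0],
        2: [-50.70710678118655, -49.29289321881345],  # mean -50, sd 1
        3: [-49.70710678118655, -48.29289321881345],
        4: [-49.20710678118655, -47.79289321881345],
    }
    res = evanno_deltaK(lnpd)
    d2 = res.table.set_index("K").loc[2, "deltaK"]
    assert d2 == pytest.approx(49.0, rel=1e-9)
    assert res.best_K == 2


def test_evanno_zero_sd_reported_as_undefined():
    res = evanno_deltaK({1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]})
    assert np.isnan(res.table["deltaK"].iloc[1])


def test_evanno_requires_consecutive_ladder():
    with pytest.raises(ValueError):
        evanno_deltaK({1: [-1.0, -1.0], 3: [-2.0, -2.0], 4: [-3.0, -3.0]})


def test_assign_clusters_argmax_and_ties():
    consensus = ConsensusAssignment(
        q=np.array([[0.9, 0.1], [0.5, 0.5]]),
        ci90_lower=np.zeros((2, 2)),
        ci90_upper=np.ones((2, 2)),
        n_runs=1,
        label_permutations=[(0, 1)],
        individual_ids=["a", "b"],
    )
    labels, ties = assign_clusters(consensus)
    assert labels.tolist() == [0, 0]  # tie broken toward lowest index
    assert ties.tolist() == [False, True]


def test_desk_config_preset():
    cfg = desk_config(K=3, seed=1)
    assert (cfg.burn_in, cfg.length, cfg.thin, cfg.K) == (5000, 20000, 10, 3)
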