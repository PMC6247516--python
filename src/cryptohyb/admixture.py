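"""Bayesian admixture clustering of multilocus genotypes (Gibbs sampler).

The model: each of K clusters has its own allele-frequency vector per locus;
each individual i has ancestry proportions q_i ~ Dirichlet(alpha, ..., alpha);
each allele copy independently originates from cluster k with probability
q_ik and is then a draw from that cluster's frequencies.  Cluster
frequencies follow the correlated-frequencies prior (F-model): cluster k's
frequencies at locus l are Dirichlet(p_A(l) * (1 - F_k) / F_k) around an
ancestral vector p_A(l), with a per-cluster drift parameter F_k.

Updates are the standard data-augmentation Gibbs moves (allele-copy origins
Z, ancestries Q, cluster frequencies P are conjugate) with random-walk
Metropolis steps for alpha, the drift parameters F_k and the ancestral
frequencies.  Missing genotypes contribute no likelihood terms.

Model evidence is estimated per run as ``lnPD = mean(lnL) - var(lnL)/2``
from the retained log-likelihood trace; the Evanno second-difference
statistic on lnPD across K selects the number of clusters, and multiple
runs are aligned by label permutation and averaged into a consensus.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from cryptohyb.genodata import GenotypeMatrix


@dataclass
class McmcConfig:
    """MCMC settings.  Defaults are full-scale study settings; use
    :func:`desk_config` for settings that run in seconds."""

    K: int = 2
    burn_in: int = 300_000
    length: int = 1_000_000
    thin: int = 100
    seed: int | None = None
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_prop_sd: float = 0.025
    f_init: float = 0.01
    f_prop_sd: float = 0.05
    # gamma prior on each cluster's drift F (mean 0.01, sd 0.05 -> shape
    # 0.04, scale 0.25, the cited program's default); None = uniform(0,1)
    f_prior: tuple[float, float] | None = (0.01, 0.05)

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.length <= 0:
            raise ValueError("burn_in and length must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def desk_config(K: int = 2, seed: int | None = None, **kw) -> McmcConfig:
    """Reduced-scale preset (burn-in 5,000, length 20,000, thin 10)."""
    kw.setdefault("burn_in", 5_000)
    kw.setdefault("length", 20_000)
    kw.setdefault("thin", 10)
    return McmcConfig(K=K, seed=seed, **kw)


@dataclass
class RunResult:
    q_mean: np.ndarray  # (n, K)
    q_ci90: tuple[np.ndarray, np.ndarray]  # lower, upper, each (n, K)
    P_mean: np.ndarray  # (K, L, Jmax)
    alpha_trace: np.ndarray
    loglik_trace: np.ndarray
    lnPD: float
    individual_ids: list[str] = field(default_factory=list)
    f_trace: np.ndarray | None = None  # (n_samples, K) drift parameters

    @property
    def K(self) -> int:
        return self.q_mean.shape[1]


@dataclass
class ConsensusAssignment:
    q: np.ndarray  # (n, K)
    ci90_lower: np.ndarray
    ci90_upper: np.ndarray
    n_runs: int
    label_permutations: list[tuple[int, ...]]
    individual_ids: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.q.shape[1]


@dataclass
class EvannoTable:
    table: "object"  # pandas DataFrame: K, mean_lnPD, sd_lnPD, deltaK
    best_K: int


def _encode(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Map allele codes to 0-based indices per locus; missing -> -1.

    Returns (codes array (n, L, 2), per-locus allele count J)."""
    n, L = gm.n_individuals, gm.n_loci
    X = np.full((n, L, 2), -1, dtype=np.int64)
    J = np.zeros(L, dtype=np.int64)
    for l in range(L):
        col = gm.alleles[:, l, :]
        obs = col != gm.missing_code
        codes = np.unique(col[obs])
        J[l] = max(len(codes), 1)
        if len(codes):
            lookup = {c: j for j, c in enumerate(codes.tolist())}
            X[:, l, :][obs] = np.vectorize(lookup.get)(col[obs])
    return X, J


def _f_prior_logpdf(f: float, prior: tuple[float, float] | None) -> float:
    if prior is None:
        return 0.0 if 0 < f < 1 else -np.inf
    mean, sd = prior
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    if not (0 < f < 1):
        return -np.inf
    return float((shape - 1) * np.log(f) - f / scale)


def run_admixture(gm: GenotypeMatrix, cfg: McmcConfig) -> RunResult:
    """Run one MCMC chain and return posterior summaries.

    Retained samples are taken every ``thin`` sweeps after ``burn_in``;
    the 90% credibility interval is the central 5th-95th percentile band
    of the retained q samples.
    """
    n, L = gm.n_individuals, gm.n_loci
    K = cfg.K
    if K > n:
        raise ValueError(f"K={K} exceeds the number of individuals ({n})")
    rng = np.random.default_rng(cfg.seed)
    X, J = _encode(gm)
    Jmax = int(J.max())
    obs = X >= 0  # (n, L, 2)
    all_missing = ~obs.any(axis=(1, 2))
    if all_missing.any():
        bad = [gm.individual_ids[i] for i in np.flatnonzero(all_missing)]
        warnings.warn(
            f"{len(bad)} individual(s) with no amplified loci (e.g. {bad[0]!r}): "
            "their q is the prior posterior"
        )
    Xc = np.where(obs, X, 0)  # clipped codes for safe gathers
    l_idx = np.arange(L)[None, :, None]

    pad = np.zeros((L, Jmax), dtype=bool)  # True on real allele slots
    for l in range(L):
        pad[l, : J[l]] = True

    # --- initial state
    alpha = float(cfg.alpha_init)
    F = np.full(K, cfg.f_init)
    # ancestral frequencies: posterior draw from pooled counts, Dir(1) prior
    counts0 = np.zeros((L, Jmax))
    flat = (X[obs] + (np.broadcast_to(np.arange(L)[None, :, None], X.shape)[obs]) * Jmax)
    np.add.at(counts0.reshape(-1), flat, 1.0)
    PA = rng.standard_gamma(np.where(pad, counts0 + 1.0, 0.0))
    PA /= PA.sum(axis=1, keepdims=True)
    P = np.empty((K, L, Jmax))
    for k in range(K):
        g = rng.standard_gamma(np.where(pad, counts0 + 1.0, 0.0))
        P[k] = g / g.sum(axis=1, keepdims=True)
    Q = np.full((n, K), 1.0 / K)

    total = cfg.burn_in + cfg.length
    n_keep = cfg.length // cfg.thin
    q_samples = np.empty((n_keep, n, K))
    loglik = np.empty(n_keep)
    alpha_trace = np.empty(n_keep)
    f_trace = np.empty((n_keep, K))
    P_running = np.zeros((K, L, Jmax))
    kept = 0

    two_allele_loci = np.flatnonzero(J >= 2)

    for sweep in range(total):
        # 1) allele-copy origins Z | Q, P  (and the data log-likelihood)
        P_x = P[:, l_idx, Xc]  # (K, n, L, 2)
        w = Q.T[:, :, None, None] * P_x
        wsum = w.sum(axis=0)
        if K > 1:
            u = rng.random((n, L, 2)) * wsum
            cdf = np.cumsum(w, axis=0)
            Z = np.minimum((u[None] > cdf).sum(axis=0), K - 1)
        else:
            Z = np.zeros((n, L, 2), dtype=np.int64)

        # 2) ancestry proportions Q | Z
        cnt = np.empty((n, K))
        for k in range(K):
            cnt[:, k] = ((Z == k) & obs).sum(axis=(1, 2))
        g = rng.standard_gamma(alpha + cnt)
        Q = g / g.sum(axis=1, keepdims=True)

        # 3) cluster frequencies P | Z  under the F-model Dirichlet prior
        C = np.zeros(K * L * Jmax)
        zidx = Z[obs] * (L * Jmax) + flat
        np.add.at(C, zidx, 1.0)
        C = C.reshape(K, L, Jmax)
        lam = ((1 - F) / F)[:, None, None] * PA[None, :, :]
        shape = np.where(pad[None], lam + C, 0.0)
        g = rng.standard_gamma(shape)
        P = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
        logP = np.log(np.clip(P, 1e-300, None))

        # 4) drift parameters F_k | P, PA (random-walk Metropolis)
        for k in range(K):
            c_cur = (1 - F[k]) / F[k]
            f_new = F[k] + rng.normal(0, cfg.f_prop_sd)
            if not (0 < f_new < 1):
                continue
            c_new = (1 - f_new) / f_new

            def f_loglik(c: float) -> float:
                lamk = np.where(pad, c * PA, 0.0)
                return float(
                    L * gammaln(c)
                    - gammaln(np.where(pad, lamk, 1.0)).sum()
                    + ((lamk - 1) * np.where(pad, logP[k], 0.0)).sum()
                )

            logr = (
                f_loglik(c_new)
                - f_loglik(c_cur)
                + _f_prior_logpdf(f_new, cfg.f_prior)
                - _f_prior_logpdf(F[k], cfg.f_prior)
            )
            if np.log(rng.random()) < logr:
                F[k] = f_new

        # 5) ancestral frequencies PA | P, F (pairwise Metropolis per locus)
        if len(two_allele_loci):
            ls = two_allele_loci
            j1 = (rng.random(len(ls)) * J[ls]).astype(np.int64)
            j2 = (j1 + 1 + (rng.random(len(ls)) * (J[ls] - 1)).astype(np.int64)) % J[ls]
            delta = rng.normal(0, 0.05, size=len(ls))
            pa1, pa2 = PA[ls, j1], PA[ls, j2]
            new1, new2 = pa1 + delta, pa2 - delta
            valid = (new1 > 0) & (new2 > 0) & (new1 < 1) & (new2 < 1)
            cK = (1 - F) / F  # (K,)
            lp1, lp2 = logP[:, ls, j1], logP[:, ls, j2]  # (K, |ls|)
            logr = np.where(valid, 0.0, -np.inf)
            for k in range(K):
                logr = logr + np.where(
                    valid,
                    -gammaln(np.clip(cK[k] * new1, 1e-12, None))
                    - gammaln(np.clip(cK[k] * new2, 1e-12, None))
                    + gammaln(cK[k] * pa1)
                    + gammaln(cK[k] * pa2)
                    + cK[k] * (new1 - pa1) * lp1[k]
                    + cK[k] * (new2 - pa2) * lp2[k],
                    0.0,
                )
            accept = np.log(rng.random(len(ls))) < logr
            PA[ls[accept], j1[accept]] = new1[accept]
            PA[ls[accept], j2[accept]] = new2[accept]

        # 6) alpha | Q (random-walk Metropolis, uniform(0, alpha_max) prior)
        if K > 1:
            a_new = alpha + rng.normal(0, cfg.alpha_prop_sd)
            if 0 < a_new < cfg.alpha_max:
                slogq = np.log(np.clip(Q, 1e-300, None)).sum()
                ll_cur = n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * slogq
                ll_new = n * (gammaln(K * a_new) - K * gammaln(a_new)) + (a_new - 1) * slogq
                if np.log(rng.random()) < ll_new - ll_cur:
                    alpha = a_new

        # 7) retain
        if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            q_samples[kept] = Q
            loglik[kept] = np.log(np.clip(wsum, 1e-300, None))[obs].sum()
            alpha_trace[kept] = alpha
            f_trace[kept] = F
            P_running += P
            kept += 1

    q_samples = q_samples[:kept]
    loglik = loglik[:kept]
    alpha_trace = alpha_trace[:kept]
    q_mean = q_samples.mean(axis=0)
    q_lo = np.percentile(q_samples, 5, axis=0)
    q_hi = np.percentile(q_samples, 95, axis=0)
    lnPD = float(loglik.mean() - loglik.var(ddof=0) / 2)
    return RunResult(
        q_mean=q_mean,
        q_ci90=(q_lo, q_hi),
        P_mean=P_running / max(kept, 1),
        alpha_trace=alpha_trace,
        loglik_trace=loglik,
        lnPD=lnPD,
        individual_ids=list(gm.individual_ids),
        f_trace=f_trace[:kept],
    )


def run_replicates(
    gm: GenotypeMatrix, cfg: McmcConfig, n_runs: int, seed: int | None = None
) -> list[RunResult]:
    """Run ``n_runs`` independent chains with seeds derived from ``seed``."""
    root = np.random.default_rng(seed if seed is not None else cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=n_runs)
    return [run_admixture(gm, replace(cfg, seed=int(s))) for s in seeds]


# ---------------------------------------------------------------------------
# multi-run consensus and model selection


def _best_permutation(ref_q: np.ndarray, q: np.ndarray) -> tuple[int, ...]:
    """Column permutation of q minimizing total |q - ref| (exact for K <= 6)."""
    K = ref_q.shape[1]
    if K > 6:
        # greedy column matching for larger K
        remaining = list(range(K))
        perm = []
        for k in range(K):
            costs = [np.abs(ref_q[:, k] - q[:, j]).sum() for j in remaining]
            pick = remaining[int(np.argmin(costs))]
            perm.append(pick)
            remaining.remove(pick)
        return tuple(perm)
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        cost = np.abs(ref_q - q[:, perm]).sum()
        if cost < best_cost:
            best, best_cost = perm, cost
    return best


def align_runs(runs: list[RunResult]) -> ConsensusAssignment:
    """Align cluster labels across runs and average into a consensus.

    The first run is the reference; each other run's columns are permuted to
    minimize the summed absolute q difference, then q and the CI bounds are
    averaged element-wise.
    """
    if not runs:
        raise ValueError("need at least one run")
    K = runs[0].K
    n = runs[0].q_mean.shape[0]
    for r in runs:
        if r.K != K or r.q_mean.shape[0] != n:
            raise ValueError("runs disagree in n or K")
    ref = runs[0].q_mean
    perms = [_best_permutation(ref, r.q_mean) for r in runs]
    q = np.mean([r.q_mean[:, p] for r, p in zip(runs, perms)], axis=0)
    lo = np.mean([r.q_ci90[0][:, p] for r, p in zip(runs, perms)], axis=0)
    hi = np.mean([r.q_ci90[1][:, p] for r, p in zip(runs, perms)], axis=0)
    return ConsensusAssignment(
        q=q,
        ci90_lower=lo,
        ci90_upper=hi,
        n_runs=len(runs),
        label_permutations=perms,
        individual_ids=list(runs[0].individual_ids),
    )


def evanno_deltaK(lnpd_by_K: dict[int, list[float]]) -> EvannoTable:
    """Evanno second-difference statistic over a ladder of K values.

    ``deltaK(K) = |mean lnPD(K+1) - 2 mean lnPD(K) + mean lnPD(K-1)| / sd(K)``
    for interior K.  Requires >= 3 consecutive K with >= 2 runs each.  A zero
    sd leaves deltaK undefined (NaN) at that K.  ``best_K`` is the argmax of
    deltaK; if every deltaK is undefined, the K with highest mean lnPD.
    """
    import pandas as pd

    Ks = sorted(lnpd_by_K)
    if len(Ks) < 3 or any(b - a != 1 for a, b in zip(Ks, Ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(lnpd_by_K[k]) < 2 for k in Ks):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(lnpd_by_K[k])) for k in Ks}
    sd = {k: float(np.std(lnpd_by_K[k], ddof=1)) for k in Ks}
    delta = {}
    for k in Ks[1:-1]:
        second = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        delta[k] = second / sd[k] if sd[k] > 0 else np.nan
    table = pd.DataFrame(
        {
            "K": Ks,
            "mean_lnPD": [mean[k] for k in Ks],
            "sd_lnPD": [sd[k] for k in Ks],
            "deltaK": [delta.get(k, np.nan) for k in Ks],
        }
    )
    finite = {k: v for k, v in delta.items() if np.isfinite(v)}
    if finite:
        best = max(finite, key=finite.get)
    else:
        best = max(mean, key=mean.get)
    return EvannoTable(table=table, best_K=int(best))


def assign_clusters(consensus: ConsensusAssignment):
    """Hard labels by argmax q; ties broken by the lowest cluster index.

    Returns (labels array of cluster indices, tie flags array)."""
    q = consensus.q
    labels = q.argmax(axis=1)
    ties = (q == q.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return labels, ties
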