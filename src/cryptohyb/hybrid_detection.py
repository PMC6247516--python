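"""Simulation-calibrated hybrid detection from admixture q-values.

Procedure: pick the highest-q individuals of each cluster as reference
parents; simulate genotypes for parental, F1, F2 and first-generation
backcross classes from the parents' empirical allele frequencies; cluster
the simulants pooled together; set per-cluster thresholds TP1/TP2 equal to
the lowest q reached by a simulated parent in each cluster; then classify
real individuals as parent or hybrid by comparing either their posterior
mean q (conservative) or the lower bound of their 90% credibility interval
(relaxed) to the threshold of their majority cluster.  A replicated
misclassification study quantifies how often pure parental simulants are
wrongly flagged as hybrids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cryptohyb.admixture import (
    ConsensusAssignment,
    McmcConfig,
    align_runs,
    run_admixture,
)
from cryptohyb.genodata import GenotypeMatrix

CLASSES = ("parentalA", "parentalB", "F1", "F2", "BC_A", "BC_B")


@dataclass
class HybridSimConfig:
    n_reference_parents: int = 80
    class_counts: dict[str, int] = field(
        default_factory=lambda: {c: 300 for c in CLASSES}
    )
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        for c, v in self.class_counts.items():
            if c not in CLASSES:
                raise ValueError(f"unknown hybrid class {c!r}")
            if v < 0:
                raise ValueError("class counts must be >= 0")


def misclassification_class_counts() -> dict[str, int]:
    """The replicated-study composition: 300 per parental class, 10 F1,
    15 backcrosses to each parental form."""
    return {"parentalA": 300, "parentalB": 300, "F1": 10, "F2": 0, "BC_A": 15, "BC_B": 15}


@dataclass
class ThresholdPair:
    TP1: float  # lowest simulated-parent q in cluster 1 (A)
    TP2: float  # lowest simulated-parent q in cluster 2 (B)


@dataclass
class HybridClassification:
    """Per-individual parent/hybrid calls under both decision rules."""

    table: pd.DataFrame  # id, q1, q2, ci_lower (majority cluster), labels

    @property
    def conservative_hybrids(self) -> list[str]:
        t = self.table
        return t.loc[t["conservative"] == "hybrid", "id"].tolist()

    @property
    def relaxed_hybrids(self) -> list[str]:
        t = self.table
        return t.loc[t["relaxed"] == "hybrid", "id"].tolist()


def select_reference_parents(
    consensus: ConsensusAssignment, n: int = 80
) -> tuple[list[str], list[str]]:
    """The n individuals with the highest q in each of the two clusters.

    Individuals belong to the cluster where their q is highest; within a
    cluster they are ranked by that q, ties broken by id order.  A cluster
    smaller than n yields all of its members with a warning.
    """
    if consensus.K != 2:
        raise ValueError("reference-parent selection requires K = 2")
    ids = np.asarray(consensus.individual_ids)
    q = consensus.q
    out = []
    for k in (0, 1):
        members = np.flatnonzero(q.argmax(axis=1) == k)
        if len(members) < n:
            warnings.warn(
                f"cluster {k + 1} has only {len(members)} members (< {n}); taking all"
            )
        ranked = sorted(members, key=lambda i: (-q[i, k], ids[i]))
        out.append([str(ids[i]) for i in ranked[:n]])
    return out[0], out[1]


def _pool_frequencies(gm: GenotypeMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per locus: (allele codes, empirical frequencies) from a parent pool."""
    freqs = []
    for l, name in enumerate(gm.locus_names):
        col = gm.alleles[:, l, :]
        obsv = col[col != gm.missing_code]
        if obsv.size == 0:
            raise ValueError(f"locus {name!r} has no amplified genotypes in a parent pool")
        codes, counts = np.unique(obsv, return_counts=True)
        freqs.append((codes, counts / counts.sum()))
    return freqs


def simulate_hybrid_classes(
    parentsA: GenotypeMatrix,
    parentsB: GenotypeMatrix,
    cfg: HybridSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Simulate genotypes for the requested hybrid classes (gamete semantics).

    A gamete from pool X draws one allele per locus from X's empirical
    frequencies; an F1 gamete draws, independently per locus, from pool A or
    pool B with probability 1/2 (one crossover-free meiosis of an
    A-gamete x B-gamete individual).  Then: parental = two pool gametes,
    F1 = one gamete from each pool, F2 = two F1 gametes, BC_X = one F1
    gamete and one pool-X gamete.  Simulants carry no missing data.
    """
    if parentsA.locus_names != parentsB.locus_names:
        raise ValueError("parent pools must share the same loci")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fA = _pool_frequencies(parentsA)
    fB = _pool_frequencies(parentsB)
    L = parentsA.n_loci

    def pool_gamete(freqs, m):
        out = np.empty((m, L), dtype=np.int64)
        for l, (codes, p) in enumerate(freqs):
            out[:, l] = rng.choice(codes, size=m, p=p)
        return out

    def f1_gamete(m):
        pick_a = rng.random((m, L)) < 0.5
        return np.where(pick_a, pool_gamete(fA, m), pool_gamete(fB, m))

    blocks = []
    labels: list[str] = []
    ids: list[str] = []
    counter = 0
    for cls in CLASSES:
        m = int(cfg.class_counts.get(cls, 0))
        if m == 0:
            continue
        if cls == "parentalA":
            g1, g2 = pool_gamete(fA, m), pool_gamete(fA, m)
        elif cls == "parentalB":
            g1, g2 = pool_gamete(fB, m), pool_gamete(fB, m)
        elif cls == "F1":
            g1, g2 = pool_gamete(fA, m), pool_gamete(fB, m)
        elif cls == "F2":
            g1, g2 = f1_gamete(m), f1_gamete(m)
        elif cls == "BC_A":
            g1, g2 = f1_gamete(m), pool_gamete(fA, m)
        else:  # BC_B
            g1, g2 = f1_gamete(m), pool_gamete(fB, m)
        blocks.append(np.stack([g1, g2], axis=2))
        labels.extend([cls] * m)
        ids.extend(f"sim{counter + i:05d}_{cls}" for i in range(m))
        counter += m
    if not blocks:
        raise ValueError("all class counts are zero: nothing to simulate")
    alleles = np.concatenate(blocks, axis=0)
    return GenotypeMatrix(ids, list(parentsA.locus_names), alleles), labels


def _orient_to_A(consensus: ConsensusAssignment, labels: list[str]) -> int:
    """Index of the consensus cluster corresponding to parental pool A."""
    lab = np.asarray(labels)
    isA = lab == "parentalA"
    if not isA.any():
        raise ValueError("no parentalA simulants to orient the clusters")
    return int(consensus.q[isA].mean(axis=0).argmax())


def calibrate_thresholds(
    consensus: ConsensusAssignment, labels: list[str]
) -> ThresholdPair:
    """TP1/TP2 = the lowest q reached by a simulated parent in each cluster.

    ``consensus`` is the clustering of the pooled simulants; ``labels`` their
    true classes.  Cluster orientation is resolved by the parental-A
    simulants' mean q.
    """
    lab = np.asarray(labels)
    if not (lab == "parentalA").any() or not (lab == "parentalB").any():
        raise ValueError("calibration requires parental simulants of both clusters")
    kA = _orient_to_A(consensus, labels)
    kB = 1 - kA
    tp1 = float(consensus.q[lab == "parentalA", kA].min())
    tp2 = float(consensus.q[lab == "parentalB", kB].min())
    return ThresholdPair(TP1=tp1, TP2=tp2)


def classify(
    consensus: ConsensusAssignment, thresholds: ThresholdPair
) -> HybridClassification:
    """Parent/hybrid calls against TP1/TP2 under both decision rules.

    An individual whose majority cluster is k is a parent of cluster k when
    its comparison value reaches TP_k, else a hybrid.  The conservative rule
    compares the posterior mean q of the majority cluster; the relaxed rule
    compares the 90% credibility interval's lower bound in that cluster, so
    every conservative hybrid is also a relaxed hybrid.
    """
    if consensus.K != 2:
        raise ValueError("classification requires K = 2")
    if consensus.ci90_lower is None:
        raise ValueError("relaxed classification requires credibility bounds")
    q = consensus.q
    tp = np.array([thresholds.TP1, thresholds.TP2])
    rows = []
    for i, ind in enumerate(consensus.individual_ids):
        k = int(q[i].argmax())
        ci_lo = float(consensus.ci90_lower[i, k])
        conservative = f"parent_{k + 1}" if q[i, k] >= tp[k] else "hybrid"
        relaxed = f"parent_{k + 1}" if ci_lo >= tp[k] else "hybrid"
        rows.append((ind, float(q[i, 0]), float(q[i, 1]), ci_lo, conservative, relaxed))
    return HybridClassification(
        table=pd.DataFrame(
            rows, columns=["id", "q1", "q2", "ci_lower", "conservative", "relaxed"]
        )
    )


def misclassification_study(
    parentsA: GenotypeMatrix,
    parentsB: GenotypeMatrix,
    thresholds: ThresholdPair,
    cfg: HybridSimConfig | None = None,
    mcmc: McmcConfig | None = None,
    n_replicates: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicated study of parental simulants wrongly flagged as hybrids.

    Per replicate: simulate the class mix (default 300 per parental class,
    10 F1, 15 backcrosses each), cluster the pooled simulants at K = 2, and
    classify the parental simulants against the *supplied* thresholds.
    Returns a per-replicate table of conservative and relaxed
    false-positive counts and rates.
    """
    from cryptohyb.admixture import desk_config

    cfg = cfg if cfg is not None else HybridSimConfig(
        class_counts=misclassification_class_counts()
    )
    mcmc = mcmc if mcmc is not None else desk_config()
    root = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        sim, labels = simulate_hybrid_classes(parentsA, parentsB, cfg, rng=rep_rng)
        run = run_admixture(
            sim, replace(mcmc, K=2, seed=int(root.integers(0, 2**31 - 1)))
        )
        consensus = align_runs([run])
        # keep TP1 attached to whichever cluster holds the A parents
        kA = _orient_to_A(consensus, labels)
        if kA == 0:
            oriented = thresholds
        else:
            oriented = ThresholdPair(TP1=thresholds.TP2, TP2=thresholds.TP1)
        calls = classify(consensus, oriented)
        lab = np.asarray(labels)
        parental = np.isin(lab, ["parentalA", "parentalB"])
        n_par = int(parental.sum())
        cons = (calls.table["conservative"].to_numpy() == "hybrid") & parental
        relx = (calls.table["relaxed"].to_numpy() == "hybrid") & parental
        rows.append(
            (rep, n_par, int(cons.sum()), int(relx.sum()),
             cons.sum() / n_par, relx.sum() / n_par)
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "replicate", "n_parental",
            "n_conservative_fp", "n_relaxed_fp",
            "rate_conservative", "rate_relaxed",
        ],
    )
    df.attrs["overall_rate_conservative"] = float(
        df["n_conservative_fp"].sum() / df["n_parental"].sum()
    )
    df.attrs["overall_rate_relaxed"] = float(
        df["n_relaxed_fp"].sum() / df["n_parental"].sum()
    )
    return df
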