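"""End-to-end orchestration: cluster -> screen -> hybrids -> stats -> mtDNA
-> phenotypes, from a single config with one global seed.

Stage seeds are derived deterministically from the global seed and the
stage name, so any stage can be re-run in isolation and a full run is
reproducible byte-for-byte.  The stage order mirrors the study design:
clusters are first defined on all loci, loci failing the null-allele or
Hardy-Weinberg screens (in either species) are dropped, clustering is
re-run on the retained loci, and all downstream analyses use those.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cryptohyb import admixture, hybrid_detection, mtdna, phenotypes, popgen_stats
from cryptohyb.genodata import GenotypeMatrix, metadata_to_frame, validate_dataset
from cryptohyb.synthetic_data import SimulationConfig, simulate_dataset


@dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    genotypes_path: str | None = None
    genotypes_dialect: str = "csv_wide"
    fasta_path: str | None = None
    metadata_path: str | None = None
    K_range: tuple[int, int] = (1, 4)
    n_runs: int = 3
    mcmc: admixture.McmcConfig = field(default_factory=admixture.desk_config)
    hybrid_sim: hybrid_detection.HybridSimConfig = field(
        default_factory=hybrid_detection.HybridSimConfig
    )
    n_perm: int = 1000
    run_ld_test: bool = False
    run_misclassification: bool = False
    misclassification_replicates: int = 30
    haplogroup_cutoff: float = 0.02
    outlier_iqr_k: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.genotypes_path is None:
            raise ValueError("either a simulation config or input paths are required")
        if self.simulate is not None and self.genotypes_path is not None:
            raise ValueError("give either a simulation config or input paths, not both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            if isinstance(sim, dict):
                for key in ("n_per_species", "drift_F", "mt_introgression_prob",
                            "coi_diversity_within", "coi_n_sequenced", "alleles_per_locus",
                            "sessions"):
                    if key in sim and isinstance(sim[key], list):
                        sim[key] = tuple(sim[key])
                raw["simulate"] = SimulationConfig(**sim)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = admixture.McmcConfig(**raw["mcmc"])
        if "hybrid_sim" in raw and isinstance(raw["hybrid_sim"], dict):
            raw["hybrid_sim"] = hybrid_detection.HybridSimConfig(**raw["hybrid_sim"])
        if "K_range" in raw and isinstance(raw["K_range"], list):
            raw["K_range"] = tuple(raw["K_range"])
        return cls(**raw)


@dataclass
class Report:
    """Consolidated pipeline output; every number is a module result."""

    dataset: dict
    evanno: dict
    consensus_summary: dict
    retained_loci: list[str]
    excluded_loci: list[str]
    thresholds: dict
    hybrids: dict
    locus_summary: list[dict]
    theta: dict
    discordance: dict | None
    phenotype_results: dict
    misclassification: dict | None
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        text = json.dumps(asdict(self), indent=2, default=default, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = [
            "# Analysis report",
            "",
            f"- individuals: {self.dataset['n_individuals']}, loci: {self.dataset['n_loci']}",
            f"- amplification rate: {self.dataset['amplification_rate']:.3f}",
            f"- selected K: {self.evanno['best_K']}",
            f"- cluster sizes: {self.consensus_summary['cluster_sizes']}",
            f"- retained loci: {len(self.retained_loci)} of "
            f"{len(self.retained_loci) + len(self.excluded_loci)}"
            f" (excluded: {', '.join(self.excluded_loci) or 'none'})",
            f"- thresholds TP1={self.thresholds['TP1']:.3f}, TP2={self.thresholds['TP2']:.3f}",
            f"- hybrids: {self.hybrids['n_conservative']} conservative, "
            f"{self.hybrids['n_relaxed']} relaxed",
            f"- multilocus theta: {self.theta['theta']:.3f}"
            + (
                f" [{self.theta['ci95'][0]:.3f}-{self.theta['ci95'][1]:.3f}]95%"
                if self.theta.get("ci95")
                else ""
            ),
        ]
        if self.discordance is not None:
            lines.append(
                f"- cyto-nuclear discordance: {self.discordance['proportions']}"
                f" (asymmetric: {self.discordance['asymmetric']})"
            )
        for trait, res in self.phenotype_results.items():
            lines.append(
                f"- {trait}: group F={res['group_effect']['F']:.2f} "
                f"(df {res['group_effect']['df1']},{res['group_effect']['df2']}), "
                f"p={res['group_effect']['p']:.2g}"
            )
        return "\n".join(lines) + "\n"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def exclude_loci(
    null_scan: pd.DataFrame, hwe: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Drop loci with significant null alleles (either group, raw p < alpha)
    or a Bonferroni-significant Hardy-Weinberg departure in either group.

    Returns (retained, excluded) locus name lists; aborts when fewer than 5
    loci would remain.
    """
    all_loci = list(dict.fromkeys(null_scan["locus"].tolist()))
    bad: set[str] = set()
    for _, row in null_scan.iterrows():
        if np.isfinite(row["p_value"]) and row["p_value"] < alpha:
            bad.add(row["locus"])
    for _, row in hwe.iterrows():
        if np.isfinite(row["p_bonferroni"]) and row["p_bonferroni"] < alpha:
            bad.add(row["locus"])
    retained = [l for l in all_loci if l not in bad]
    if len(retained) < 5:
        raise RuntimeError(
            f"locus screen would retain only {len(retained)} loci; aborting"
        )
    return retained, sorted(bad)


def _cluster(gm: GenotypeMatrix, cfg: PipelineConfig, K: int, stage: str):
    mcmc = replace(cfg.mcmc, K=K)
    runs = admixture.run_replicates(gm, mcmc, cfg.n_runs, seed=stage_seed(cfg.seed, stage))
    return runs


def run_pipeline(cfg: PipelineConfig) -> Report:
    """Execute the full analysis and return a consolidated :class:`Report`."""
    # --- stage: data
    if cfg.simulate is not None:
        sim_cfg = replace(cfg.simulate, seed=stage_seed(cfg.seed, "simulate")
                          if cfg.simulate.seed is None else cfg.simulate.seed)
        gm, coi, metadata, truth = simulate_dataset(sim_cfg)
    else:
        from cryptohyb.genodata import read_fasta, read_genotypes

        gm = read_genotypes(cfg.genotypes_path, cfg.genotypes_dialect)
        coi = read_fasta(cfg.fasta_path) if cfg.fasta_path else None
        metadata = None
        if cfg.metadata_path:
            df = pd.read_csv(cfg.metadata_path)
            from cryptohyb.genodata import SampleMetadata

            metadata = [
                SampleMetadata(
                    individual_id=str(r["individual_id"]),
                    sex=str(r.get("sex", "unknown")),
                    site=str(r.get("site", "")),
                    session=str(r.get("session", "")),
                    forearm_mm=None if pd.isna(r.get("forearm_mm")) else float(r["forearm_mm"]),
                    fme_khz=None if pd.isna(r.get("fme_khz")) else float(r["fme_khz"]),
                )
                for _, r in df.iterrows()
            ]
        truth = None
    report_dataset = asdict(validate_dataset(gm, metadata))
    report_dataset.pop("issues", None)

    # --- stage: model selection over a ladder of K
    lnpd: dict[int, list[float]] = {}
    runs_by_K: dict[int, list] = {}
    for K in range(cfg.K_range[0], cfg.K_range[1] + 1):
        runs = _cluster(gm, cfg, K, f"cluster_K{K}")
        runs_by_K[K] = runs
        lnpd[K] = [r.lnPD for r in runs]
    evanno = admixture.evanno_deltaK(lnpd)
    best_K = evanno.best_K
    consensus = admixture.align_runs(runs_by_K[best_K])
    labels_idx, _ = admixture.assign_clusters(consensus)

    # --- stage: locus screens on the initial clusters
    group_labels = np.array([f"cluster{k + 1}" for k in labels_idx])
    null_scan = popgen_stats.null_allele_scan(gm, group_labels)
    hwe = popgen_stats.hwe_test(
        gm, group_labels, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "hwe")
    )
    retained, excluded = exclude_loci(null_scan, hwe)
    ld = None
    if cfg.run_ld_test:
        ld = popgen_stats.ld_test(
            gm, group_labels, n_perm=min(cfg.n_perm, 200),
            seed=stage_seed(cfg.seed, "ld"),
        )

    # --- stage: re-cluster on retained loci
    gm15 = gm.subset(loci=retained) if excluded else gm
    if excluded:
        runs = _cluster(gm15, cfg, best_K, "recluster")
        consensus = admixture.align_runs(runs)
        labels_idx, _ = admixture.assign_clusters(consensus)
    sizes = [int((labels_idx == k).sum()) for k in range(best_K)]
    consensus_summary = {
        "cluster_sizes": sizes,
        "mean_max_q": float(consensus.q.max(axis=1).mean()),
        "n_runs": consensus.n_runs,
    }

    # --- stage: hybrid detection (K = 2 path)
    thresholds_d: dict = {"TP1": float("nan"), "TP2": float("nan")}
    hybrids_d: dict = {"n_conservative": 0, "n_relaxed": 0}
    classification = None
    misclass = None
    if best_K == 2:
        idsA, idsB = hybrid_detection.select_reference_parents(
            consensus, cfg.hybrid_sim.n_reference_parents
        )
        poolA, poolB = gm15.subset(idsA), gm15.subset(idsB)
        hs_cfg = replace(cfg.hybrid_sim, seed=stage_seed(cfg.seed, "hybridize"))
        sim, sim_labels = hybrid_detection.simulate_hybrid_classes(poolA, poolB, hs_cfg)
        sim_run = admixture.run_admixture(
            sim, replace(cfg.mcmc, K=2, seed=stage_seed(cfg.seed, "sim_cluster"))
        )
        sim_consensus = admixture.align_runs([sim_run])
        tp = hybrid_detection.calibrate_thresholds(sim_consensus, sim_labels)
        classification = hybrid_detection.classify(consensus, tp)
        thresholds_d = {"TP1": tp.TP1, "TP2": tp.TP2}
        hybrids_d = {
            "n_conservative": len(classification.conservative_hybrids),
            "n_relaxed": len(classification.relaxed_hybrids),
            "conservative_ids": classification.conservative_hybrids,
            "relaxed_ids": classification.relaxed_hybrids,
        }
        if cfg.run_misclassification:
            mc = hybrid_detection.misclassification_study(
                poolA,
                poolB,
                tp,
                mcmc=cfg.mcmc,
                n_replicates=cfg.misclassification_replicates,
                seed=stage_seed(cfg.seed, "misclassification"),
            )
            misclass = {
                "overall_rate_conservative": mc.attrs["overall_rate_conservative"],
                "overall_rate_relaxed": mc.attrs["overall_rate_relaxed"],
                "n_replicates": int(len(mc)),
            }

    # --- stage: population-genetic statistics on retained loci
    group_labels = np.array([f"cluster{k + 1}" for k in labels_idx])
    summary = popgen_stats.locus_summaries(gm15, group_labels)
    theta_res = popgen_stats.wc_theta(
        gm15, group_labels, seed=stage_seed(cfg.seed, "theta")
    ) if best_K >= 2 else None
    theta_d = (
        {"theta": theta_res.theta, "ci95": theta_res.ci95, "n_boot": theta_res.n_boot}
        if theta_res
        else {"theta": float("nan"), "ci95": None, "n_boot": 0}
    )

    # --- stage: mtDNA
    discordance_d = None
    mt_labels: dict[str, str] = {}
    if coi is not None and len(coi) >= 2 and best_K == 2:
        dm = mtdna.raw_distance(coi)
        part = mtdna.haplogroup_partition(dm, cfg.haplogroup_cutoff)
        nuclear = {
            ind: f"cluster{k + 1}" for ind, k in zip(gm15.individual_ids, labels_idx)
        }
        # name each haplogroup after the nuclear cluster most common in it
        hap_name: dict[int, str] = {}
        for hg in set(part.labels.values()):
            members = [i for i, g in part.labels.items() if g == hg and i in nuclear]
            if members:
                counts = pd.Series([nuclear[i] for i in members]).value_counts()
                hap_name[hg] = str(counts.index[0])
            else:
                hap_name[hg] = f"hap{hg}"
        mt_labels = {i: hap_name[g] for i, g in part.labels.items()}
        disc = mtdna.cytonuclear_discordance(
            {i: nuclear[i] for i in mt_labels if i in nuclear}, mt_labels
        )
        discordance_d = {
            "table": {str(k): v for k, v in disc.table.to_dict().items()},
            "proportions": {f"{a}->{b}": p for (a, b), p in disc.proportions.items()},
            "asymmetric": disc.asymmetric,
            "within_means": {str(k): v for k, v in part.within_means.items()},
            "between_mean": part.between_mean,
        }

    # --- stage: phenotypes (hybrids and mt-discordant individuals excluded)
    phen_d: dict = {}
    if metadata is not None and best_K == 2:
        meta = metadata_to_frame(metadata)
        nuclear_s = pd.Series(
            [f"cluster{k + 1}" for k in labels_idx], index=gm15.individual_ids
        )
        excluded_ids: set[str] = set()
        if classification is not None:
            excluded_ids |= set(classification.relaxed_hybrids)
        for ind, mt_lab in mt_labels.items():
            if ind in nuclear_s.index and mt_lab != nuclear_s[ind]:
                excluded_ids.add(ind)
        keep = [i for i in gm15.individual_ids if i not in excluded_ids and i in meta.index]
        sub = meta.loc[keep]
        grp = nuclear_s.loc[keep]
        for trait, col in (("forearm", "forearm_mm"), ("fme", "fme_khz")):
            vals = sub[col]
            out_ids = phenotypes.screen_outliers(vals, grp, k=cfg.outlier_iqr_k)
            vals = vals.drop(index=out_ids)
            try:
                res = phenotypes.nested_anova(vals, sub["sex"].loc[vals.index], grp.loc[vals.index])
            except ValueError as exc:
                phen_d[trait] = {"error": str(exc)}
                continue
            phen_d[trait] = {
                "group_effect": asdict(res.group_effect),
                "sex_any": asdict(res.sex_any),
                "interaction": asdict(res.interaction),
                "posthoc": [asdict(p) for p in res.posthoc],
                "group_means": res.group_means,
                "n": res.n,
                "outliers_removed": [str(i) for i in out_ids],
            }

    return Report(
        dataset=report_dataset,
        evanno={
            "best_K": best_K,
            "table": evanno.table.to_dict(orient="records"),
        },
        consensus_summary=consensus_summary,
        retained_loci=retained,
        excluded_loci=excluded,
        thresholds=thresholds_d,
        hybrids=hybrids_d,
        locus_summary=summary.to_dict(orient="records"),
        theta=theta_d,
        discordance=discordance_d,
        phenotype_results=phen_d,
        misclassification=misclass,
        provenance={
            "seed": cfg.seed,
            "n_runs": cfg.n_runs,
            "mcmc": {
                "burn_in": cfg.mcmc.burn_in,
                "length": cfg.mcmc.length,
                "thin": cfg.mcmc.thin,
            },
            "ld_test": None if ld is None else int(ld["significant"].sum()),
        },
    )
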