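"""Simulation-calibrated hybrid detection.

Selects the 80 highest-q individuals per cluster as reference parents,
simulates parental/F1/F2/backcross classes from their allele frequencies,
clusters the pooled simulants to calibrate the TP1/TP2 thresholds (lowest
simulated-parent q per cluster), and classifies every real individual as
parent or hybrid under the conservative (mean q) and relaxed (90% CI lower
bound) rules.  With --replicates N it also runs the N-replicate parental
misclassification study at the {300, 300, 10, 15, 15} class mix.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import MCMC, RESULTS, SEED, announce, load_dataset, load_labels, save_table

from cryptohyb.admixture import ConsensusAssignment, McmcConfig, align_runs, run_admixture
from cryptohyb.hybrid_detection import (
    HybridSimConfig,
    calibrate_thresholds,
    classify,
    misclassification_class_counts,
    misclassification_study,
    select_reference_parents,
    simulate_hybrid_classes,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=0,
                    help="misclassification replicates (0 = skip; the study used 30)")
    args = ap.parse_args()

    gm, *_ = load_dataset()
    import numpy as np

    _, q = load_labels()
    q = q.loc[gm.individual_ids]
    consensus = ConsensusAssignment(
        q=q[["q1", "q2"]].to_numpy(),
        ci90_lower=q[["ci1_lower", "ci2_lower"]].to_numpy(),
        ci90_upper=np.minimum(q[["q1", "q2"]].to_numpy() + 0.1, 1.0),
        n_runs=1,
        label_permutations=[(0, 1)],
        individual_ids=gm.individual_ids,
    )
    idsA, idsB = select_reference_parents(consensus, 80)
    poolA, poolB = gm.subset(idsA), gm.subset(idsB)

    sim, labels = simulate_hybrid_classes(poolA, poolB, HybridSimConfig(seed=SEED))
    run = run_admixture(sim, McmcConfig(K=2, seed=SEED + 1, **MCMC))
    tp = calibrate_thresholds(align_runs([run]), labels)
    calls = classify(consensus, tp)
    save_table(calls.table, "hybrid_classification.tsv")
    (RESULTS / "thresholds.json").write_text(json.dumps({"TP1": tp.TP1, "TP2": tp.TP2}))

    lines = [
        f"thresholds TP1 = {tp.TP1:.3f}, TP2 = {tp.TP2:.3f}",
        f"{len(calls.conservative_hybrids)} conservative / "
        f"{len(calls.relaxed_hybrids)} relaxed putative hybrids of {gm.n_individuals}",
    ]
    if args.replicates:
        df = misclassification_study(
            poolA, poolB, tp,
            cfg=HybridSimConfig(class_counts=misclassification_class_counts()),
            mcmc=McmcConfig(K=2, **MCMC),
            n_replicates=args.replicates, seed=SEED + 2,
        )
        save_table(df, "misclassification.tsv")
        lines.append(
            f"misclassification over {args.replicates} replicates: "
            f"conservative {df.attrs['overall_rate_conservative']:.4f}, "
            f"relaxed {df.attrs['overall_rate_relaxed']:.4f}"
        )
    announce("04_hybrid_detection", *lines)


if __name__ == "__main__":
    main()
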