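"""Population-genetic statistics on the retained loci.

Per-locus, per-species Na/Ho/He/Fis with global per-locus Fst (the study's
marker table), multilocus Weir-Cockerham theta with a bootstrap-over-loci
CI, pairwise cave differentiation with exact-G permutation tests, and the
F_ST-based sex-biased dispersal test within each species.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
from common import RESULTS, SEED, announce, load_dataset, load_labels, save_table

from cryptohyb.popgen_stats import (
    locus_summaries,
    pairwise_fst,
    sex_biased_dispersal_test,
    wc_theta,
)


def main() -> None:
    gm, _, meta, _ = load_dataset()
    labels, _ = load_labels()
    retained = json.loads((RESULTS / "retained_loci.json").read_text())
    gm = gm.subset(loci=retained)
    lab = labels.loc[gm.individual_ids].to_numpy()
    meta = meta.loc[gm.individual_ids]

    summary = locus_summaries(gm, lab)
    save_table(summary, "locus_summary.tsv")
    theta = wc_theta(gm, lab, n_boot=1000, seed=SEED)
    mean_na = summary.groupby("group")["Na"].mean()

    lines = [
        f"multilocus theta = {theta.theta:.3f} "
        f"[{theta.ci95[0]:.3f}-{theta.ci95[1]:.3f}]95% over {len(retained)} loci",
        f"mean Na: A {mean_na.get('A', float('nan')):.2f}, B {mean_na.get('B', float('nan')):.2f}",
    ]
    for sp in ("A", "B"):
        sel = lab == sp
        sub = gm.subset([i for i, s in zip(gm.individual_ids, sel) if s])
        sites = meta.loc[sub.individual_ids, "site"].to_numpy()
        sexes = meta.loc[sub.individual_ids, "sex"].to_numpy()
        cave = pairwise_fst(sub, sites, n_perm=200, seed=SEED)
        save_table(cave, f"cave_fst_{sp}.tsv")
        lines.append(
            f"species {sp}: cave theta range "
            f"{cave['theta'].min():.4f}..{cave['theta'].max():.4f}, "
            f"min p = {cave['p_value'].min():.3f}"
        )
        for disperser in ("M", "F"):
            res = sex_biased_dispersal_test(
                sub, sexes, sites, n_rand=1000, dispersing_sex=disperser, seed=SEED
            )
            lines.append(
                f"species {sp}, {disperser}-dispersal test: "
                f"theta_F - theta_M = {res.statistic:+.4f}, p = {res.p_value:.3f}"
            )
    announce("05_popgen_stats", *lines)


if __name__ == "__main__":
    main()
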