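"""Mitochondrial barcode analysis and cyto-nuclear discordance.

Computes raw pairwise distances on the COI alignment, partitions sequences
into haplogroups by single linkage at a 2% cutoff, summarises within- and
between-group divergence, and cross-tabulates nuclear cluster against
mitochondrial haplogroup to quantify directional introgression.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from common import RESULTS, announce, load_dataset, load_labels

from cryptohyb.mtdna import cytonuclear_discordance, haplogroup_partition, raw_distance


def main() -> None:
    _, coi, _, _ = load_dataset()
    labels, _ = load_labels()

    dm = raw_distance(coi)
    dm.to_frame().to_csv(RESULTS / "coi_distances.tsv", sep="\t")
    part = haplogroup_partition(dm, cutoff=0.02)

    nuclear = labels.loc[[i for i in coi.ids if i in labels.index]].to_dict()
    hap_name = {}
    for hg in sorted(set(part.labels.values())):
        members = [i for i in part.labels if part.labels[i] == hg and i in nuclear]
        votes = pd.Series([nuclear[i] for i in members]).value_counts()
        hap_name[hg] = votes.index[0] if len(votes) else f"hap{hg}"
    mt = {i: hap_name[g] for i, g in part.labels.items()}
    disc = cytonuclear_discordance(nuclear, mt)

    out = {
        "n_haplogroups": len(set(part.labels.values())),
        "within_means": part.within_means,
        "between_mean": part.between_mean,
        "min_between_over_max_within": float(part.min_between / part.max_within)
        if np.isfinite(part.max_within) and part.max_within > 0 else None,
        "table": {str(k): v for k, v in disc.table.to_dict().items()},
        "proportions": {f"{a}->{b}": p for (a, b), p in disc.proportions.items()},
        "asymmetric": disc.asymmetric,
    }
    (RESULTS / "discordance.json").write_text(json.dumps(out, indent=2, default=float))
    announce(
        "06_mtdna_discordance",
        f"{out['n_haplogroups']} haplogroups; within means "
        + ", ".join(f"{hap_name[g]}: {v:.4f}" for g, v in part.within_means.items())
        + f"; between {part.between_mean:.4f}",
        f"smallest between / largest within = {out['min_between_over_max_within']:.1f}",
        f"discordance {out['proportions']} (asymmetric: {disc.asymmetric})",
    )


if __name__ == "__main__":
    main()
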