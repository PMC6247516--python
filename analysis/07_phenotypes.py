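"""Nested two-way ANOVA of forearm length and call frequency.

Excludes relaxed-rule nuclear hybrids and cyto-nuclear discordant
individuals, screens for gross low outliers within groups (Q1 - 3 IQR),
then tests the group effect corrected for sex, any sex effect, and the
sex-by-group interaction, with per-group post-hoc t-tests.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import RESULTS, announce, load_dataset, load_labels

from cryptohyb.phenotypes import nested_anova, screen_outliers


def main() -> None:
    gm, coi, meta, _ = load_dataset()
    labels, _ = load_labels()
    calls = pd.read_csv(RESULTS / "hybrid_classification.tsv", sep="\t", index_col="id")
    disc = json.loads((RESULTS / "discordance.json").read_text())

    excluded = set(calls.index[calls["relaxed"] == "hybrid"])
    # also exclude sequenced individuals whose haplogroup disagrees with
    # their nuclear cluster (cyto-nuclear discordant)
    part_ids = [i for i in coi.ids if i in labels.index]
    from cryptohyb.mtdna import haplogroup_partition, raw_distance

    part = haplogroup_partition(raw_distance(coi), cutoff=0.02)
    hap_name = {}
    for hg in sorted(set(part.labels.values())):
        members = [i for i in part.labels if part.labels[i] == hg and i in labels.index]
        votes = pd.Series(labels.loc[members]).value_counts()
        hap_name[hg] = votes.index[0] if len(votes) else f"hap{hg}"
    for i in part_ids:
        if hap_name[part.labels[i]] != labels[i]:
            excluded.add(i)

    keep = [i for i in gm.individual_ids if i not in excluded]
    meta = meta.loc[keep]
    grp = labels.loc[keep]
    lines = [f"excluded {len(excluded)} putative hybrid / discordant individuals"]
    results = {}
    for trait, col in (("forearm", "forearm_mm"), ("fme", "fme_khz")):
        vals = meta[col]
        out_ids = screen_outliers(vals, grp)
        vals = vals.drop(index=out_ids)
        res = nested_anova(vals, meta["sex"].loc[vals.index], grp.loc[vals.index])
        results[trait] = {
            "n": res.n,
            "group_means": res.group_means,
            "group_effect": vars(res.group_effect),
            "sex_any": vars(res.sex_any),
            "interaction": vars(res.interaction),
            "posthoc": [vars(p) for p in res.posthoc],
            "outliers_removed": list(map(str, out_ids)),
        }
        sig = {p.group: p for p in res.posthoc}
        lines += [
            f"{trait}: means A {res.group_means.get('A', float('nan')):.2f} / "
            f"B {res.group_means.get('B', float('nan')):.2f}; group effect "
            f"F = {res.group_effect.F:.2f} (df {res.group_effect.df1},{res.group_effect.df2}), "
            f"p = {res.group_effect.p:.2g}",
            f"{trait}: sex-by-group interaction F = {res.interaction.F:.2f} "
            f"(p = {res.interaction.p:.2g}); post-hoc "
            + "; ".join(
                f"{g}: t = {p.t:.2f}, p = {p.p:.2g} ({p.direction})"
                for g, p in sig.items()
            ),
        ]
    (RESULTS / "phenotypes.json").write_text(json.dumps(results, indent=2, default=float))
    announce("07_phenotypes", *lines)


if __name__ == "__main__":
    main()
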