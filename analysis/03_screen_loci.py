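"""Locus quality screens: null alleles and Hardy-Weinberg departures.

Runs the Chakraborty null-allele scan with an exact binomial test for
homozygote excess, and the Weir-Cockerham-f permutation test for HWE with
Bonferroni correction, per locus within each species cluster; loci failing
either screen in either cluster are excluded from downstream analyses.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import json

from common import RESULTS, SEED, announce, load_dataset, load_labels, save_table

from cryptohyb.pipeline import exclude_loci
from cryptohyb.popgen_stats import hwe_test, ld_test, null_allele_scan


def main() -> None:
    gm, *_ = load_dataset()
    labels, _ = load_labels()
    lab = labels.loc[gm.individual_ids].to_numpy()

    null_scan = null_allele_scan(gm, lab)
    hwe = hwe_test(gm, lab, n_perm=2000, seed=SEED)
    ld = ld_test(gm, lab, n_perm=200, seed=SEED)
    retained, excluded = exclude_loci(null_scan, hwe)

    save_table(null_scan, "null_allele_scan.tsv")
    save_table(hwe, "hwe_tests.tsv")
    save_table(ld, "ld_tests.tsv")
    (RESULTS / "retained_loci.json").write_text(json.dumps(retained))
    announce(
        "03_screen_loci",
        f"null-allele flags: {sorted(set(null_scan[null_scan.p_value < 0.05].locus))}",
        f"HWE flags (Bonferroni): {sorted(set(hwe[hwe.significant].locus))}",
        f"LD pairs significant: {int(ld['significant'].sum())}",
        f"retained {len(retained)} of {gm.n_loci} loci -> {RESULTS / 'retained_loci.json'}",
    )


if __name__ == "__main__":
    main()
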