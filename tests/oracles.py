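"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's own code paths: explicit loops,
literal transcriptions of the published formulas, and closed-form cell-mean
arithmetic.
"""

import numpy as np

from cryptohyb.genodata import AlignedSequences, GenotypeMatrix


def wc_theta_literal(gm: GenotypeMatrix, labels) -> float:
    """Literal loop transcription of the Weir & Cockerham (1984) estimator:
    per locus and allele, a = (nbar/nc)(s2 - (p(1-p) - (r-1)/r s2 - h/4)/(nbar-1)),
    b = nbar/(nbar-1) (p(1-p) - (r-1)/r s2 - (2nbar-1)/(4nbar) h), c = h/2;
    theta = sum a / sum(a+b+c)."""
    labels = list(labels)
    groups = sorted(set(labels))
    A_sum = ABC_sum = 0.0
    for l in range(gm.n_loci):
        data = {}
        for g in groups:
            pairs = [
                tuple(gm.alleles[i, l, :])
                for i in range(gm.n_individuals)
                if labels[i] == g and gm.alleles[i, l, 0] != gm.missing_code
            ]
            if len(pairs) >= 2:
                data[g] = pairs
        r = len(data)
        if r < 2:
            continue
        ns = [len(data[g]) for g in data]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for pairs in data.values() for p in pairs for a in p})
        for al in alleles:
            ps, hs = [], []
            for g in data:
                pairs = data[g]
                n = len(pairs)
                ps.append(sum(int(p[0] == al) + int(p[1] == al) for p in pairs) / (2 * n))
                hs.append(sum(int(p[0] == al) != int(p[1] == al) for p in pairs) / n)
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            A_sum += a
            ABC_sum += a + b + c
    return A_sum / ABC_sum


def raw_distance_bruteforce(seqs: AlignedSequences) -> np.ndarray:
    """Per-site loop comparison with pairwise deletion of non-ACGT sites."""
    n = len(seqs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = comp = 0
            for x, y in zip(seqs.sequences[i], seqs.sequences[j]):
                if x in "ACGT" and y in "ACGT":
                    comp += 1
                    diff += x != y
            out[i, j] = out[j, i] = diff / comp if comp else np.nan
    return out


def anova_f_oracle(y, sex, group):
    """Nested-model F statistics from explicit residual sums of squares.

    Cell-mean models (group, sex, full) use closed-form group means; the
    additive model solves its normal equations directly.  Returns the
    (group_effect, sex_any, interaction) F values.
    """
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex)
    group = np.asarray(group)

    def rss_by_cells(keys) -> float:
        total = 0.0
        for key in set(map(tuple, keys)):
            sel = np.array([tuple(k) == key for k in keys])
            total += ((y[sel] - y[sel].mean()) ** 2).sum()
        return total

    rss_group = rss_by_cells(list(zip(group)))
    rss_sex = rss_by_cells(list(zip(sex)))
    rss_full = rss_by_cells(list(zip(sex, group)))

    s = (sex == "M").astype(float)
    g = (group == sorted(set(group.tolist()), key=str)[1]).astype(float)
    X = np.column_stack([np.ones_like(y), s, g])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss_add = float(((y - X @ beta) ** 2).sum())

    df_full = len(y) - 4
    mse = rss_full / df_full
    f_group = (rss_sex - rss_add) / 1 / mse
    f_sex_any = (rss_group - rss_full) / 2 / mse
    f_inter = (rss_add - rss_full) / 1 / mse
    return f_group, f_sex_any, f_inter
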