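"""Population-genetic estimators and permutation tests for microsatellites.

Implements the Weir & Cockerham (1984) variance-component estimators of
F_ST (theta) and F_IS (f), per-locus diversity summaries (Na, Ho, unbiased
He), permutation tests for Hardy-Weinberg equilibrium and linkage
disequilibrium, null-allele screening (Chakraborty / Brookfield estimators
with an exact binomial test for homozygote excess), pairwise-population
differentiation with G log-likelihood permutation tests, and an
F_ST-based sex-biased dispersal randomization test.

All permutation p-values use the includes-observed convention
``p = (b + 1) / (m + 1)`` where ``b`` counts null statistics at least as
extreme as the observed one over ``m`` randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest

from cryptohyb.genodata import GenotypeMatrix


@dataclass
class FstResult:
    """Multilocus Weir-Cockerham theta with a bootstrap-over-loci CI."""

    theta: float
    per_locus_theta: list[float]
    ci95: tuple[float, float] | None
    n_boot: int


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    tail: str  # lower, upper or two-sided


def bonferroni(p: np.ndarray | pd.Series, k: int | None = None):
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    arr = np.asarray(p, dtype=float)
    k = k if k is not None else np.isfinite(arr).sum()
    out = np.minimum(arr * max(int(k), 1), 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


# ---------------------------------------------------------------------------
# internal helpers


def _group_arrays(gm: GenotypeMatrix, labels) -> tuple[list[np.ndarray], list]:
    """Split the allele array by group label, preserving label sort order."""
    labels = np.asarray(labels)
    if labels.shape[0] != gm.n_individuals:
        raise ValueError("labels length does not match the genotype matrix")
    uniq = sorted(set(labels.tolist()))
    return [gm.alleles[labels == g] for g in uniq], uniq


def _locus_freq_het(block: np.ndarray, l: int, missing: int):
    """For one group at one locus: (n_i, allele codes, freqs, het freqs per allele).

    ``het freq`` of allele j is the fraction of amplified individuals carrying
    exactly one copy of j (the h_i of Weir & Cockerham).
    """
    pair = block[:, l, :]
    keep = pair[:, 0] != missing
    pair = pair[keep]
    n = pair.shape[0]
    if n == 0:
        return 0, np.array([], dtype=np.int64), np.array([]), np.array([])
    codes = np.unique(pair)
    freqs = np.array([(pair == j).sum() for j in codes], dtype=float) / (2 * n)
    het = np.array(
        [((pair[:, 0] == j) != (pair[:, 1] == j)).sum() for j in codes], dtype=float
    ) / n
    return n, codes, freqs, het


def _wc_components_locus(gm: GenotypeMatrix, labels, l: int):
    """Weir-Cockerham (1984) variance components a, b, c summed over alleles
    at locus ``l``, using only groups with >= 2 amplified individuals."""
    blocks, _ = _group_arrays(gm, labels)
    per_group = []
    all_codes: set[int] = set()
    for blk in blocks:
        n, codes, freqs, het = _locus_freq_het(blk, l, gm.missing_code)
        if n >= 2:
            per_group.append((n, dict(zip(codes.tolist(), freqs)), dict(zip(codes.tolist(), het))))
            all_codes.update(codes.tolist())
    r = len(per_group)
    if r < 2 or not all_codes:
        return np.nan, np.nan, np.nan
    ns = np.array([g[0] for g in per_group], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for j in sorted(all_codes):
        p = np.array([g[1].get(j, 0.0) for g in per_group])
        h = np.array([g[2].get(j, 0.0) for g in per_group])
        pbar = (ns * p).sum() / (r * nbar)
        s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def wc_components(gm: GenotypeMatrix, labels) -> pd.DataFrame:
    """Per-locus a, b, c components (summed over alleles) as a DataFrame."""
    rows = [_wc_components_locus(gm, labels, l) for l in range(gm.n_loci)]
    return pd.DataFrame(rows, columns=["a", "b", "c"], index=gm.locus_names)


def _fis_single_group(n: int, freqs: np.ndarray, het: np.ndarray) -> float:
    """Weir-Cockerham f for a single sample (the r = 1 limit of b and c)."""
    if n < 2:
        return np.nan
    b = (n / (n - 1)) * (freqs * (1 - freqs) - (2 * n - 1) / (4 * n) * het)
    c = het / 2
    denom = (b + c).sum()
    if denom <= 0:
        return np.nan
    return float(1 - c.sum() / denom)


# ---------------------------------------------------------------------------
# diversity summaries


def locus_summaries(gm: GenotypeMatrix, labels) -> pd.DataFrame:
    """Per-locus, per-group Na / Ho / He / Fis plus the global per-locus Fst.

    He is Nei's unbiased estimator ``2n/(2n-1) * (1 - sum p^2)``; Fis is the
    single-sample Weir-Cockerham f; Fst is the per-locus ratio
    ``a / (a + b + c)`` over all groups.  Monomorphic loci get Fis = NaN.
    """
    blocks, uniq = _group_arrays(gm, labels)
    comp = wc_components(gm, labels)
    with np.errstate(invalid="ignore"):
        fst = comp["a"] / (comp["a"] + comp["b"] + comp["c"])
    rows = []
    for l, locus in enumerate(gm.locus_names):
        for g, blk in zip(uniq, blocks):
            n, codes, freqs, het = _locus_freq_het(blk, l, gm.missing_code)
            if n == 0:
                rows.append((locus, g, 0, np.nan, np.nan, np.nan, float(fst.iloc[l])))
                continue
            ho = float(((blk[:, l, 0] != blk[:, l, 1]) & (blk[:, l, 0] != gm.missing_code)).sum() / n)
            he = float(2 * n / (2 * n - 1) * (1 - (freqs**2).sum()))
            rows.append(
                (locus, g, int(len(codes)), ho, he, _fis_single_group(n, freqs, het), float(fst.iloc[l]))
            )
    return pd.DataFrame(
        rows, columns=["locus", "group", "Na", "Ho", "He", "Fis", "Fst"]
    )


def allelic_richness(gm: GenotypeMatrix, labels, g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per locus per group.

    Expected number of alleles in a subsample of ``g`` diploid individuals
    (default: the smallest per-group amplified sample over loci), using the
    hypergeometric rarefaction formula.
    """
    blocks, uniq = _group_arrays(gm, labels)
    sizes = []
    for blk in blocks:
        for l in range(gm.n_loci):
            n = int((blk[:, l, 0] != gm.missing_code).sum())
            if n > 0:
                sizes.append(n)
    if g is None:
        g = min(sizes)
    rows = []
    for l, locus in enumerate(gm.locus_names):
        for grp, blk in zip(uniq, blocks):
            n, codes, freqs, _ = _locus_freq_het(blk, l, gm.missing_code)
            if n < g or len(codes) == 0:
                rows.append((locus, grp, np.nan))
                continue
            counts = np.round(freqs * 2 * n).astype(int)
            N = 2 * n
            # P(allele absent from 2g draws without replacement)
            def log_c(a, b):
                return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
            rich = 0.0
            for cj in counts:
                if N - cj < 2 * g:
                    rich += 1.0
                else:
                    rich += 1.0 - np.exp(log_c(N - cj, 2 * g) - log_c(N, 2 * g))
            rows.append((locus, grp, float(rich)))
    return pd.DataFrame(rows, columns=["locus", "group", "richness"])


# ---------------------------------------------------------------------------
# theta and differentiation tests


def wc_theta(
    gm: GenotypeMatrix, labels, n_boot: int = 1000, seed: int | None = None
) -> FstResult:
    """Multilocus Weir-Cockerham theta = sum(a) / sum(a+b+c) over loci,
    with a percentile bootstrap-over-loci 95% CI."""
    comp = wc_components(gm, labels).dropna()
    if comp.empty:
        raise ValueError("theta undefined: need >= 2 groups with >= 2 amplified individuals")
    a = comp["a"].to_numpy()
    abc = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    theta = float(a.sum() / abc.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = (comp["a"] / abc).tolist()
    poly = abc > 0
    ci = None
    if poly.sum() >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        L = len(a)
        idx = rng.integers(0, L, size=(n_boot, L))
        num = a[idx].sum(axis=1)
        den = abc[idx].sum(axis=1)
        ok = den != 0
        boot = num[ok] / den[ok]
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return FstResult(theta=theta, per_locus_theta=per_locus, ci95=ci, n_boot=n_boot)


def _g_stat_alleles(gm: GenotypeMatrix, sub_labels, pair_alleles) -> float:
    """G log-likelihood statistic on allele-count tables, summed over loci.

    ``pair_alleles``: (n, L, 2) allele array restricted to the two groups;
    ``sub_labels``: 0/1 group index per individual.
    """
    G = 0.0
    missing = gm.missing_code
    for l in range(pair_alleles.shape[1]):
        pair = pair_alleles[:, l, :]
        keep = pair[:, 0] != missing
        if keep.sum() == 0:
            continue
        lab = sub_labels[keep]
        flat = pair[keep].ravel()
        labs2 = np.repeat(lab, 2)
        codes = np.unique(flat)
        if len(codes) < 2:
            continue
        table = np.zeros((len(codes), 2))
        for j, code in enumerate(codes):
            table[j, 0] = ((flat == code) & (labs2 == 0)).sum()
            table[j, 1] = ((flat == code) & (labs2 == 1)).sum()
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        obs = table[table > 0]
        exp = expected[table > 0]
        G += 2 * (obs * np.log(obs / exp)).sum()
    return float(G)


def pairwise_fst(
    gm: GenotypeMatrix, labels, n_perm: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Pairwise theta between groups plus exact-G permutation p-values.

    The G statistic is computed on per-locus allele-count tables and the null
    is built by permuting multilocus genotypes between the two groups.
    Groups of fewer than 2 individuals are excluded with a warning entry.
    """
    import warnings

    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    sizes = {g: int((labels == g).sum()) for g in uniq}
    kept = [g for g in uniq if sizes[g] >= 2]
    for g in uniq:
        if g not in kept:
            warnings.warn(f"group {g!r} has fewer than 2 individuals; excluded")
    rng = np.random.default_rng(seed)
    rows = []
    for i, g1 in enumerate(kept):
        for g2 in kept[i + 1 :]:
            sel = (labels == g1) | (labels == g2)
            sub = GenotypeMatrix(
                [gm.individual_ids[k] for k in np.flatnonzero(sel)],
                gm.locus_names,
                gm.alleles[sel],
                gm.missing_code,
            )
            sub_lab = (labels[sel] == g2).astype(int)
            theta = wc_theta(sub, sub_lab, n_boot=0).theta
            g_obs = _g_stat_alleles(sub, sub_lab, sub.alleles)
            b = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_lab)
                if _g_stat_alleles(sub, perm, sub.alleles) >= g_obs:
                    b += 1
            rows.append((g1, g2, theta, (b + 1) / (n_perm + 1)))
    return pd.DataFrame(rows, columns=["group1", "group2", "theta", "p_value"])


# ---------------------------------------------------------------------------
# locus quality screens


def hwe_test(
    gm: GenotypeMatrix,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Permutation test for Hardy-Weinberg departure per locus per group.

    Statistic: single-sample Weir-Cockerham f.  Null distribution: the
    group's alleles at the locus are randomly re-paired into genotypes
    (allele permutation).  ``alternative`` is 'two-sided' or 'deficit'
    (one-sided heterozygote deficit, f > 0).  Bonferroni-adjusted flags are
    included over all locus x group tests performed.
    """
    if alternative not in ("two-sided", "deficit"):
        raise ValueError("alternative must be 'two-sided' or 'deficit'")
    rng = np.random.default_rng(seed)
    blocks, uniq = _group_arrays(gm, labels)
    rows = []
    for l, locus in enumerate(gm.locus_names):
        for g, blk in zip(uniq, blocks):
            n, codes, freqs, het = _locus_freq_het(blk, l, gm.missing_code)
            if n < 5 or len(codes) < 2:
                rows.append((locus, g, np.nan, np.nan))
                continue
            f_obs = _fis_single_group(n, freqs, het)
            pair = blk[:, l, :]
            pool = pair[pair[:, 0] != gm.missing_code].ravel()
            m = len(pool) // 2
            # f depends on the pairing only through the total heterozygote
            # count, since allele frequencies are permutation-invariant
            S_p = (freqs * (1 - freqs)).sum()
            tiled = np.tile(pool, (n_perm, 1))
            perms = rng.permuted(tiled, axis=1).reshape(n_perm, m, 2)
            H = 2 * (perms[:, :, 0] != perms[:, :, 1]).sum(axis=1) / m
            denom = m / (m - 1) * (S_p - (2 * m - 1) / (4 * m) * H) + H / 2
            with np.errstate(invalid="ignore", divide="ignore"):
                f_null = 1 - (H / 2) / denom
            if alternative == "deficit":
                b = int((f_null >= f_obs).sum())
            else:
                b = int((np.abs(f_null) >= abs(f_obs)).sum())
            rows.append((locus, g, f_obs, (b + 1) / (n_perm + 1)))
    df = pd.DataFrame(rows, columns=["locus", "group", "fis", "p_value"])
    df["p_bonferroni"] = bonferroni(df["p_value"])
    df["significant"] = df["p_bonferroni"] < 0.05
    return df


def _genotype_codes(pair: np.ndarray) -> np.ndarray:
    """Encode unordered allele pairs as integer genotype ids."""
    lo = np.minimum(pair[:, 0], pair[:, 1])
    hi = np.maximum(pair[:, 0], pair[:, 1])
    _, codes = np.unique(np.stack([lo, hi], axis=1), axis=0, return_inverse=True)
    return codes


def _g_stat_table(x: np.ndarray, y: np.ndarray) -> float:
    """G statistic on the contingency table of two integer code vectors."""
    kx, ky = x.max() + 1, y.max() + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (x, y), 1.0)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    tot = table.sum()
    if tot == 0:
        return 0.0
    expected = rowsum * colsum / tot
    obs = table[table > 0]
    exp = expected[table > 0]
    return float(2 * (obs * np.log(obs / exp)).sum())


def ld_test(
    gm: GenotypeMatrix, labels, n_perm: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Genotypic linkage-disequilibrium permutation test per locus pair.

    Statistic: G log-likelihood on the two-locus genotype contingency table,
    summed over groups.  Null: one locus's genotypes permuted among
    individuals within each group.  Pairs with fewer than 5 complete
    genotypes in every group are reported NA.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    rows = []
    for l1 in range(gm.n_loci):
        for l2 in range(l1 + 1, gm.n_loci):
            per_group = []
            for g in uniq:
                blk = gm.alleles[labels == g]
                keep = (blk[:, l1, 0] != gm.missing_code) & (blk[:, l2, 0] != gm.missing_code)
                if keep.sum() < 5:
                    continue
                x = _genotype_codes(blk[keep][:, l1, :])
                y = _genotype_codes(blk[keep][:, l2, :])
                if x.max() == 0 or y.max() == 0:
                    continue
                per_group.append((x, y))
            if not per_group:
                rows.append((gm.locus_names[l1], gm.locus_names[l2], np.nan, np.nan))
                continue
            g_obs = sum(_g_stat_table(x, y) for x, y in per_group)
            b = 0
            for _ in range(n_perm):
                g_null = sum(
                    _g_stat_table(x, rng.permutation(y)) for x, y in per_group
                )
                if g_null >= g_obs:
                    b += 1
            rows.append(
                (gm.locus_names[l1], gm.locus_names[l2], g_obs, (b + 1) / (n_perm + 1))
            )
    df = pd.DataFrame(rows, columns=["locus1", "locus2", "G", "p_value"])
    df["p_bonferroni"] = bonferroni(df["p_value"])
    df["significant"] = df["p_bonferroni"] < 0.05
    return df


def null_allele_scan(
    gm: GenotypeMatrix, labels, estimator: str = "chakraborty"
) -> pd.DataFrame:
    """Estimate null-allele frequency per locus per group and test its
    significance with an exact binomial test for homozygote excess.

    Estimators: 'chakraborty' r = (He - Ho) / (He + Ho) or 'brookfield'
    r = (He - Ho) / (1 + He).  The binomial test compares the observed
    homozygote count against its Hardy-Weinberg expectation (one-sided
    excess).  Loci with He = 0 are reported NA.
    """
    if estimator not in ("chakraborty", "brookfield"):
        raise ValueError("estimator must be 'chakraborty' or 'brookfield'")
    blocks, uniq = _group_arrays(gm, labels)
    rows = []
    for l, locus in enumerate(gm.locus_names):
        for g, blk in zip(uniq, blocks):
            n, codes, freqs, het = _locus_freq_het(blk, l, gm.missing_code)
            if n < 10 or len(codes) == 0:
                rows.append((locus, g, np.nan, np.nan))
                continue
            pair = blk[:, l, :]
            amp = pair[pair[:, 0] != gm.missing_code]
            ho = float((amp[:, 0] != amp[:, 1]).sum() / n)
            he = float(2 * n / (2 * n - 1) * (1 - (freqs**2).sum()))
            if he <= 0:
                rows.append((locus, g, np.nan, np.nan))
                continue
            if estimator == "chakraborty":
                r = (he - ho) / (he + ho) if (he + ho) > 0 else np.nan
            else:
                r = (he - ho) / (1 + he)
            n_hom = int((amp[:, 0] == amp[:, 1]).sum())
            p_hom = float((freqs**2).sum() + (1 - (freqs**2).sum()) / (2 * n))
            p = binomtest(n_hom, n, min(p_hom, 1.0), alternative="greater").pvalue
            rows.append((locus, g, float(r), float(p)))
    return pd.DataFrame(rows, columns=["locus", "group", "null_freq", "p_value"])


# ---------------------------------------------------------------------------
# sex-biased dispersal


def sex_biased_dispersal_test(
    gm: GenotypeMatrix,
    sex_labels,
    site_labels,
    n_rand: int = 1000,
    dispersing_sex: str = "M",
    seed: int | None = None,
) -> PermutationTestResult:
    """F_ST-based sex-biased dispersal randomization test.

    Statistic: theta(females over sites) - theta(males over sites).  The
    dispersing sex is expected to show the lower among-site theta, so with
    males hypothesized to disperse the upper tail is tested, with females
    the lower tail.  Null: sex labels randomly reassigned within sites.
    Sites lacking one of the sexes are excluded with a warning.
    """
    import warnings

    if dispersing_sex not in ("M", "F"):
        raise ValueError("dispersing_sex must be 'M' or 'F'")
    sex = np.asarray(sex_labels)
    site = np.asarray(site_labels)
    known = (sex == "M") | (sex == "F")
    ok_sites = []
    for s in sorted(set(site[known].tolist())):
        in_site = known & (site == s)
        if len(set(sex[in_site].tolist())) == 2:
            ok_sites.append(s)
        else:
            warnings.warn(f"site {s!r} lacks one of the sexes; excluded")
    if len(ok_sites) < 2:
        raise ValueError("need both sexes present in >= 2 sites")
    keep = known & np.isin(site, ok_sites)
    idx = np.flatnonzero(keep)
    sub = GenotypeMatrix(
        [gm.individual_ids[i] for i in idx], gm.locus_names, gm.alleles[idx], gm.missing_code
    )
    sex_k = sex[keep]
    site_k = site[keep]

    def stat(sex_vec: np.ndarray) -> float:
        vals = []
        for s_label in ("F", "M"):
            sel = sex_vec == s_label
            try:
                vals.append(wc_theta(sub.subset([sub.individual_ids[i] for i in np.flatnonzero(sel)]), site_k[sel], n_boot=0).theta)
            except ValueError:
                return np.nan
        return vals[0] - vals[1]

    obs = stat(sex_k)
    rng = np.random.default_rng(seed)
    b = 0
    m = 0
    for _ in range(n_rand):
        perm = sex_k.copy()
        for s in ok_sites:
            in_site = site_k == s
            perm[in_site] = rng.permutation(perm[in_site])
        val = stat(perm)
        if np.isnan(val):
            continue
        m += 1
        if dispersing_sex == "M":
            b += val >= obs
        else:
            b += val <= obs
    return PermutationTestResult(
        statistic=float(obs),
        p_value=(b + 1) / (m + 1),
        n_permutations=m,
        tail="upper" if dispersing_sex == "M" else "lower",
    )
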