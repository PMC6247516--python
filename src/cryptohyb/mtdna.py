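"""Mitochondrial barcode analysis: raw distances, haplogroups, discordance.

Distances are "raw" p-distances -- the proportion of differing sites among
sites where both sequences carry an unambiguous base (pairwise deletion of
gaps and Ns).  Haplogroups are single-linkage connected components of the
distance graph at a cutoff chosen between the within- and between-group
divergence scales.  Cyto-nuclear discordance cross-tabulates nuclear cluster
labels against mitochondrial haplogroups to quantify asymmetric
introgression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from cryptohyb.genodata import AlignedSequences

_BASES = {"A", "C", "G", "T"}


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, NaN when no comparable sites
    pairwise_sites_used: np.ndarray  # integer counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class HaplogroupPartition:
    labels: dict[str, int]  # sequence id -> group index (0-based, by size desc)
    cutoff: float
    within_means: dict[int, float]
    between_mean: float
    min_between: float = np.nan
    max_within: float = np.nan


@dataclass
class DiscordanceTable:
    table: pd.DataFrame  # nuclear label x mt label counts
    proportions: dict[tuple, float] = field(default_factory=dict)
    asymmetric: bool = False


def raw_distance(seqs: AlignedSequences) -> DistanceMatrix:
    """Pairwise raw p-distance with pairwise deletion of gaps/N/ambiguities.

    Any character outside {A, C, G, T} is treated as missing at that site.
    Pairs with zero comparable sites get NaN with a warning.
    """
    n = len(seqs)
    arr = np.array([list(s) for s in seqs.sequences])
    valid = np.isin(arr, list(_BASES))
    dist = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    L = arr.shape[1]
    used[np.diag_indices(n)] = valid.sum(axis=1)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        m = both.sum(axis=1)
        diff = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(m > 0, diff / np.maximum(m, 1), np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        used[i, i + 1 :] = m
        used[i + 1 :, i] = m
    if n > 1 and np.isnan(dist[~np.eye(n, dtype=bool)]).any():
        warnings.warn("some sequence pairs share no comparable sites; distances set to NaN")
    return DistanceMatrix(list(seqs.ids), dist, used)


def haplogroup_partition(dm: DistanceMatrix, cutoff: float = 0.02) -> HaplogroupPartition:
    """Partition sequences into single-linkage groups at distance <= cutoff.

    The default cutoff of 0.02 sits an order of magnitude above typical
    within-species barcode divergence and well below between-species
    divergence.  Groups are numbered by decreasing size (ties by first id).
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    n = len(dm.ids)
    adj = np.nan_to_num(dm.values, nan=np.inf) <= cutoff
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    # renumber components by decreasing size, stable on first occurrence
    order = sorted(
        set(comp.tolist()),
        key=lambda c: (-(comp == c).sum(), int(np.flatnonzero(comp == c)[0])),
    )
    remap = {old: new for new, old in enumerate(order)}
    groups = np.array([remap[c] for c in comp])
    labels = dict(zip(dm.ids, groups.tolist()))
    within: dict[int, float] = {}
    for g in sorted(set(groups.tolist())):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            within[g] = np.nan
            continue
        sub = dm.values[np.ix_(idx, idx)]
        within[g] = float(np.nanmean(sub[np.triu_indices(len(idx), k=1)]))
    between_vals = []
    for i in range(n):
        for j in range(i + 1, n):
            if groups[i] != groups[j] and np.isfinite(dm.values[i, j]):
                between_vals.append(dm.values[i, j])
    between = float(np.mean(between_vals)) if between_vals else np.nan
    min_between = float(np.min(between_vals)) if between_vals else np.nan
    finite_within = [v for v in within.values() if np.isfinite(v)]
    max_within = float(np.max(finite_within)) if finite_within else np.nan
    return HaplogroupPartition(
        labels=labels,
        cutoff=cutoff,
        within_means=within,
        between_mean=between,
        min_between=min_between,
        max_within=max_within,
    )


def divergence_summary(seqs: AlignedSequences, groups: dict[str, object]) -> dict:
    """Mean within-group and between-group raw distances for given labels."""
    dm = raw_distance(seqs)
    ids = dm.ids
    lab = np.array([groups[i] for i in ids], dtype=object)
    out: dict = {"within": {}, "between": np.nan}
    between_vals = []
    for g in sorted(set(lab.tolist()), key=str):
        idx = np.flatnonzero(lab == g)
        if len(idx) >= 2:
            sub = dm.values[np.ix_(idx, idx)]
            out["within"][g] = float(np.nanmean(sub[np.triu_indices(len(idx), k=1)]))
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if lab[i] != lab[j] and np.isfinite(dm.values[i, j]):
                between_vals.append(dm.values[i, j])
    if between_vals:
        out["between"] = float(np.mean(between_vals))
    return out


def cytonuclear_discordance(
    nuclear_labels: dict[str, object], mt_labels: dict[str, object]
) -> DiscordanceTable:
    """Cross-tabulate nuclear vs mitochondrial assignments on shared ids.

    Returns the count table, per-direction discordance proportions
    (fraction of individuals of each nuclear group carrying each foreign
    mt haplogroup), and an asymmetry flag set when the table is 2x2 and
    exactly one off-diagonal cell is non-zero.
    """
    shared = sorted(set(nuclear_labels) & set(mt_labels))
    if not shared:
        raise ValueError("nuclear and mitochondrial label sets share no ids")
    nuc = pd.Series({i: nuclear_labels[i] for i in shared}, name="nuclear")
    mt = pd.Series({i: mt_labels[i] for i in shared}, name="mt")
    table = pd.crosstab(nuc, mt)
    proportions: dict[tuple, float] = {}
    for ng in table.index:
        total = table.loc[ng].sum()
        for mg in table.columns:
            if ng != mg and total > 0:
                proportions[(ng, mg)] = float(table.loc[ng, mg] / total)
    asymmetric = False
    if table.shape == (2, 2):
        od = [table.iloc[0, 1], table.iloc[1, 0]]
        asymmetric = (od[0] == 0) != (od[1] == 0)
    return DiscordanceTable(table=table, proportions=proportions, asymmetric=asymmetric)
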