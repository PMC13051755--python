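"""Community-assembly partitioning: betaMNTD, beta-NTI, RC-Bray, processes.

The deterministic/stochastic partition follows the two-stage null-model
framework: pairs with |betaNTI| > 2 are assigned to selection
(homogeneous if betaNTI < -2, heterogeneous if > 2); the remaining pairs
are split by Raup-Crick on Bray-Curtis (RC > 0.95 dispersal limitation,
RC < -0.95 homogenizing dispersal, otherwise drift).

betaNTI nulls shuffle tip labels across the whole tree ("taxa.labels"
randomization); one shuffle per null replicate is applied to every pair
so pair values within a replicate share the same null tree.  The RC null
assembles each community by drawing its observed richness with taxon
probability proportional to metacommunity occupancy and abundances by a
multinomial draw of the observed read total at metacommunity relative
abundances.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .io_core import CountTable, PhyloTree

log = logging.getLogger("phyllokbs")

PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------


def _weights(table: CountTable, weighted: bool) -> np.ndarray:
    if weighted:
        return table.relative_abundance()
    pres = (table.counts > 0).astype(float)
    rich = pres.sum(axis=0)
    rich[rich == 0] = 1.0
    return pres / rich


def _nearest_taxon_matrix(d: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[i, s] = min patristic distance from taxon i to any taxon in sample s."""
    n_taxa, n_samples = presence.shape
    M = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        idx = np.flatnonzero(presence[:, s])
        M[:, s] = d[:, idx].min(axis=1)
    return M


def _beta_mntd_all(d: np.ndarray, f: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """Full sample-by-sample betaMNTD matrix from a patristic matrix."""
    M = _nearest_taxon_matrix(d, presence)
    G = f.T @ M  # G[a, b] = sum_i f_ia * min_{j in b} d(i, j)
    return 0.5 * (G + G.T)


def patristic_matrix_for(table: CountTable, tree: PhyloTree) -> np.ndarray:
    """Patristic distances in the table's taxon order; errors on missing tips."""
    missing = set(table.taxon_ids) - set(tree.tip_labels)
    if missing:
        raise KeyError(
            f"{len(missing)} table taxa missing from tree, e.g. {sorted(missing)[:3]}"
        )
    return tree.patristic_matrix(table.taxon_ids)


def beta_mntd(
    table: CountTable,
    tree: PhyloTree | np.ndarray,
    pair: tuple[str, str],
    weighted: bool = True,
) -> float:
    """Abundance-weighted mean nearest-taxon distance between two samples."""
    d = tree if isinstance(tree, np.ndarray) else patristic_matrix_for(table, tree)
    a, b = (table.sample_ids.index(s) for s in pair)
    f = _weights(table, weighted)
    presence = table.counts > 0
    ia, ib = np.flatnonzero(presence[:, a]), np.flatnonzero(presence[:, b])
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("betaMNTD undefined for an empty community")
    term_a = f[ia, a] @ d[np.ix_(ia, ib)].min(axis=1)
    term_b = f[ib, b] @ d[np.ix_(ib, ia)].min(axis=1)
    return float(0.5 * (term_a + term_b))


def _all_pairs(sample_ids: list[str]) -> list[tuple[str, str]]:
    return list(combinations(sample_ids, 2))


def beta_nti(
    table: CountTable,
    tree: PhyloTree | np.ndarray,
    pairs: list[tuple[str, str]] | None = None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-pair betaNTI with tip-label-shuffle nulls.

    Returns a frame with observed betaMNTD, null mean/sd and the z-score
    ``bnti`` (NaN with a warning when the null sd is zero, e.g. on a star
    tree where the metric is permutation-invariant).
    """
    d = tree if isinstance(tree, np.ndarray) else patristic_matrix_for(table, tree)
    if pairs is None:
        pairs = _all_pairs(table.sample_ids)
    f = _weights(table, weighted)
    presence = table.counts > 0
    obs = _beta_mntd_all(d, f, presence)

    rng = np.random.default_rng(seed)
    n_taxa = table.n_taxa
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_all(d[np.ix_(perm, perm)], f, presence)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var * n_null / max(n_null - 1, 1))

    idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    n_degenerate = 0
    for a, b in pairs:
        i, j = idx[a], idx[b]
        if sd[i, j] <= 1e-12:
            bnti = np.nan
            n_degenerate += 1
        else:
            bnti = (obs[i, j] - mean[i, j]) / sd[i, j]
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "betamntd": obs[i, j],
                "null_mean": mean[i, j],
                "null_sd": sd[i, j],
                "bnti": bnti,
            }
        )
    if n_degenerate:
        log.warning("beta_nti: %d pair(s) with zero null sd reported as NaN", n_degenerate)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RC-Bray
# ---------------------------------------------------------------------------


def rc_bray(
    table: CountTable,
    pairs: list[tuple[str, str]] | None = None,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Raup-Crick on Bray-Curtis, rescaled to [-1, 1].

    RC = 2 * ((#{null < obs} + 0.5 * #{null = obs}) / n_null - 0.5).
    Null replicates are drawn once per sample and shared across pairs.
    """
    if pairs is None:
        pairs = _all_pairs(table.sample_ids)
    counts = table.counts
    n_taxa, n_samples = counts.shape
    occupancy = (counts > 0).sum(axis=1).astype(float)
    p_meta = table.relative_abundance().mean(axis=1)
    pool = np.flatnonzero(occupancy > 0)
    occ_p = occupancy[pool] / occupancy[pool].sum()

    rng = np.random.default_rng(seed)
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    nulls = np.zeros((n_null, n_taxa, n_samples), dtype=np.int32)
    for s in range(n_samples):
        r, tot = int(richness[s]), int(totals[s])
        if r == 0:
            continue
        for k in range(n_null):
            chosen = pool[rng.choice(len(pool), size=r, replace=False, p=occ_p)]
            pp = p_meta[chosen]
            pp = pp / pp.sum()
            nulls[k, chosen, s] = rng.multinomial(tot, pp)

    x = counts.astype(float)
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for a, b in pairs:
        i, j = idx[a], idx[b]
        denom = (x[:, i] + x[:, j]).sum()
        obs = np.abs(x[:, i] - x[:, j]).sum() / denom if denom > 0 else 0.0
        na, nb = nulls[:, :, i].astype(float), nulls[:, :, j].astype(float)
        ndenom = (na + nb).sum(axis=1)
        ndenom[ndenom == 0] = 1.0
        null_d = np.abs(na - nb).sum(axis=1) / ndenom
        less = (null_d < obs - 1e-12).sum()
        equal = (np.abs(null_d - obs) <= 1e-12).sum()
        rc = 2.0 * ((less + 0.5 * equal) / n_null - 0.5)
        rows.append({"sample_a": a, "sample_b": b, "bray_curtis": obs, "rc_bray": rc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Process partition
# ---------------------------------------------------------------------------


def classify_process(bnti: float, rc: float) -> str:
    """Ecological process from (betaNTI, RC-Bray) thresholds."""
    if np.isnan(bnti):
        return "unclassified"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if np.isnan(rc):
        return "unclassified"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def partition(bnti_df: pd.DataFrame, rc_df: pd.DataFrame) -> pd.DataFrame:
    """Merge betaNTI and RC frames and assign the process per pair."""
    merged = bnti_df.merge(rc_df, on=["sample_a", "sample_b"], how="left")
    merged["process"] = [
        classify_process(b, r)
        for b, r in zip(merged["bnti"], merged.get("rc_bray", np.nan))
    ]
    return merged


def process_fractions(partitioned: pd.DataFrame) -> pd.Series:
    """Relative importance: fraction of classified pairs per process."""
    classified = partitioned[partitioned["process"] != "unclassified"]
    frac = classified["process"].value_counts(normalize=True)
    return frac.reindex(PROCESSES, fill_value=0.0)


def within_group_pairs(sample_ids: list[str], groups) -> list[tuple[str, str]]:
    """All unordered pairs of samples sharing a group label."""
    if hasattr(groups, "loc"):
        groups = {s: groups.loc[s] for s in sample_ids}
    pairs = []
    for a, b in combinations(sample_ids, 2):
        if groups[a] == groups[b]:
            pairs.append((a, b))
    return pairs


def between_group_pairs(sample_ids: list[str], groups) -> list[tuple[str, str]]:
    if hasattr(groups, "loc"):
        groups = {s: groups.loc[s] for s in sample_ids}
    return [
        (a, b) for a, b in combinations(sample_ids, 2) if groups[a] != groups[b]
    ]


def assembly_analysis(
    table: CountTable,
    tree: PhyloTree | np.ndarray,
    groups,
    pair_mode: str = "within",
    n_null: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """betaNTI + RC-Bray + partition over the chosen pair set.

    ``pair_mode``: 'within' (pairs inside each group — the default group
    contrast), 'between', or 'all'.
    """
    if pair_mode == "within":
        pairs = within_group_pairs(table.sample_ids, groups)
    elif pair_mode == "between":
        pairs = between_group_pairs(table.sample_ids, groups)
    elif pair_mode == "all":
        pairs = _all_pairs(table.sample_ids)
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    bnti_df = beta_nti(table, tree, pairs, n_null=n_null, seed=seed)
    rc_df = rc_bray(table, pairs, n_null=n_null, seed=seed + 1)
    part = partition(bnti_df, rc_df)
    return part, process_fractions(part)
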