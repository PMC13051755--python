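"""Levins niche breadth with a fixed-margin permutation null.

B = 1 / sum_j p_j^2 where p_j is the share of a taxon's reads found in
sample j; B ranges from 1 (all reads in one sample — extreme specialist)
to the number of samples (perfectly even — extreme generalist).  The
null keeps every taxon total and every sample total fixed by sampling
contingency tables uniformly at those margins (Patefield's algorithm);
taxa below the null 2.5% quantile are specialists, above the 97.5%
quantile generalists, otherwise neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import CountTable
from .stats import AnovaLSD, TwoGroupTest, anova_lsd, two_group_t

log = logging.getLogger("phyllokbs")

LABELS = ("specialist", "neutral_taxon", "generalist")


def levins_b(counts_for_taxon) -> float:
    """Levins niche breadth of one taxon's per-sample count vector."""
    x = np.asarray(counts_for_taxon, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("levins_b undefined for an all-zero vector")
    p = x / total
    return float(1.0 / (p @ p))


def _levins_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise Levins B; rows with zero total return NaN."""
    totals = matrix.sum(axis=1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = matrix / totals[:, None]
        b = 1.0 / np.einsum("ij,ij->i", p, p)
    b[totals <= 0] = np.nan
    return b


@dataclass
class NicheClassification:
    table: pd.DataFrame  # per taxon: b_obs, null_mean, q025, q975, label, single_sample
    n_perm: int

    def labels(self) -> pd.Series:
        return self.table["label"]

    def taxa_with_label(self, label: str) -> set[str]:
        return set(self.table.index[self.table["label"] == label])

    def label_fractions(self) -> pd.Series:
        return self.table["label"].value_counts(normalize=True).reindex(
            LABELS, fill_value=0.0
        )


def classify_niche(table: CountTable, n_perm: int = 1000, seed: int = 0) -> NicheClassification:
    """Specialist / neutral / generalist labels against a fixed-fixed null.

    All-zero taxa are excluded; taxa occurring in a single sample are
    classifiable (B = 1) but flagged ``single_sample`` since their null
    distribution is nearly degenerate.
    """
    if n_perm < 100:
        log.warning("classify_niche: n_perm=%d is low; quantiles will be coarse", n_perm)
    counts = table.counts
    keep = counts.sum(axis=1) > 0
    matrix = counts[keep, :]
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    b_obs = _levins_rows(matrix)

    rng = np.random.default_rng(seed)
    row_sums = matrix.sum(axis=1)
    col_sums = matrix.sum(axis=0)
    dist = sps.random_table(row_sums, col_sums)
    null_b = np.empty((n_perm, len(taxa)))
    # draw in blocks to bound memory on large tables
    block = max(1, min(n_perm, int(2e8 // max(matrix.size, 1))))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        tables = dist.rvs(k, method="patefield", random_state=rng)
        if k == 1:
            tables = tables[None, ...] if tables.ndim == 2 else tables
        for i in range(k):
            null_b[done + i] = _levins_rows(tables[i])
        done += k

    q025 = np.nanquantile(null_b, 0.025, axis=0)
    q975 = np.nanquantile(null_b, 0.975, axis=0)
    null_mean = np.nanmean(null_b, axis=0)
    label = np.where(
        b_obs < q025, "specialist", np.where(b_obs > q975, "generalist", "neutral_taxon")
    )
    single = (matrix > 0).sum(axis=1) == 1
    df = pd.DataFrame(
        {
            "b_obs": b_obs,
            "null_mean": null_mean,
            "q025": q025,
            "q975": q975,
            "label": label,
            "single_sample": single,
        },
        index=taxa,
    )
    return NicheClassification(df, n_perm)


def compare_breadth(
    class_a: NicheClassification,
    class_b: NicheClassification,
    labels=("A", "B"),
) -> dict:
    """t-test on per-taxon B between two communities."""
    a = class_a.table["b_obs"].dropna().to_numpy()
    b = class_b.table["b_obs"].dropna().to_numpy()
    test: TwoGroupTest = two_group_t(a, b)
    return {
        "mean_b": {labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        "t": test.statistic,
        "p": test.p_value,
        "method": test.method,
    }


def breadth_by_group(table: CountTable, groups, n_perm: int = 1000, seed: int = 0) -> AnovaLSD:
    """Mean Levins B of each sample subgroup (e.g. CS/CR/FS/FR), ANOVA+LSD.

    B is recomputed on each subgroup's sample subset, and the per-taxon
    values are compared across subgroups.
    """
    if hasattr(groups, "loc"):
        groups = {s: groups.loc[s] for s in table.sample_ids}
    by_group: dict[str, np.ndarray] = {}
    for g in sorted(set(groups.values())):
        sids = [s for s in table.sample_ids if groups[s] == g]
        sub = table.select_samples(sids)
        keep = sub.counts.sum(axis=1) > 0
        by_group[g] = _levins_rows(sub.counts[keep, :])
    return anova_lsd(by_group)
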