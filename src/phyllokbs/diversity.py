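"""Alpha richness, Bray-Curtis dissimilarity, PCoA and PERMANOVA.

PCoA is the classical Gower-centred eigendecomposition of -D^2/2;
negative eigenvalues (Bray-Curtis is not Euclidean) are dropped and the
discarded mass logged.  PERMANOVA follows the distance-partition
pseudo-F with free label permutation and the add-one p convention
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountTable

log = logging.getLogger("phyllokbs")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.abs(np.diag(self.values)) > 1e-12).any():
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def pcoa1(self) -> np.ndarray:
        return self.coordinates[:, 0]


def richness(table: CountTable) -> pd.Series:
    """Observed OTU count (taxa with count > 0) per sample."""
    return pd.Series(
        (table.counts > 0).sum(axis=0), index=table.sample_ids, name="richness"
    )


def bray_curtis(table: CountTable, relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis: sum|x-y| / sum(x+y).

    ``relative=True`` computes on column-normalised frequencies rather
    than raw (typically rarefied) counts.
    """
    x = table.relative_abundance() if relative else table.counts.astype(float)
    n = table.n_samples
    d = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(x[:, j:] - x[:, j : j + 1]).sum(axis=0)
        tot = (x[:, j:] + x[:, j : j + 1]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(tot > 0, diff / tot, 0.0)
        d[j, j:] = row
        d[j:, j] = row
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d)


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis; negative eigenvalues dropped."""
    D2 = d.values**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    G = (G + G.T) / 2
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    neg_mass = -evals[evals < -tol].sum()
    if neg_mass > 0:
        log.info(
            "pcoa: dropping negative-eigenvalue mass %.4g (%.2f%% of positive mass)",
            neg_mass, 100 * neg_mass / evals[pos].sum(),
        )
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    denom = np.abs(evals).sum()
    prop = evals[pos] / denom if denom > 0 else evals[pos]
    return Ordination(list(d.sample_ids), coords, evals[pos], prop)


def _group_indicators(grouping: np.ndarray) -> list[np.ndarray]:
    return [grouping == g for g in np.unique(grouping)]


def _pseudo_f(D2: np.ndarray, masks: list[np.ndarray]) -> tuple[float, float]:
    n = D2.shape[0]
    g = len(masks)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for m in masks:
        ng = int(m.sum())
        ss_within += D2[np.ix_(m, m)].sum() / (2 * ng)
    ss_between = ss_total - ss_within
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    d: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0
) -> dict[str, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` is a sequence of labels aligned with ``d.sample_ids``
    (or a mapping / pandas Series indexed by sample id).
    """
    if hasattr(grouping, "loc"):
        grouping = np.asarray([grouping.loc[s] for s in d.sample_ids])
    elif isinstance(grouping, dict):
        grouping = np.asarray([grouping[s] for s in d.sample_ids])
    else:
        grouping = np.asarray(grouping)
    labels, counts = np.unique(grouping, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    D2 = d.values**2
    masks = _group_indicators(grouping)
    f_obs, r2 = _pseudo_f(D2, masks)

    n = len(grouping)
    g = len(labels)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_labels = grouping[perms]  # (n_perm, n)
    ss_total = D2.sum() / (2 * n)
    ss_within = np.zeros(n_perm)
    for lab, ng in zip(labels, counts):
        Z = (perm_labels == lab).astype(float)
        ss_within += np.einsum("pi,pi->p", Z @ D2, Z) / (2 * ng)
    ss_between = ss_total - ss_within
    f_perm = (ss_between / (g - 1)) / (ss_within / (n - g))
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    return {"pseudo_F": float(f_obs), "R2": float(r2), "p": float(p), "n_perm": n_perm}
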