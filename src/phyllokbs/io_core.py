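"""Shared domain types and tabular/tree I/O for the phyllosphere pipeline.

The pipeline operates on OTU count tables (taxa x samples), a taxonomy
assignment table, a rooted phylogeny with branch lengths, per-sample
metadata (cultivar, resistance class, fertilization, replicate, yield,
soil chemistry) and a list of putatively beneficial taxa.  Everything is
plain TSV / newick so a study can be assembled from standard upstream
outputs (QIIME-style OTU tables, SILVA/UNITE taxonomy exports).

Internally, count tables are canonically taxa-as-rows.  On read the
orientation is auto-detected (taxa usually vastly outnumber samples) and
can be forced with ``orientation_hint``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger("phyllokbs")

Kingdom = Literal["bacteria", "fungi"]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes/QIIME-style rank prefixes stripped from taxonomy strings.
_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Integer abundance matrix, taxa as rows, samples as columns."""

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    kingdom: Kingdom = "bacteria"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SchemaError("counts must be a 2-D matrix")
        if self.counts.size == 0:
            raise SchemaError("empty count table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise SchemaError("non-integer counts in table")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise SchemaError("negative counts in table")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.taxon_ids) != self.counts.shape[0]:
            raise SchemaError("taxon_ids length does not match matrix rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise SchemaError("sample_ids length does not match matrix columns")
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise SchemaError(f"duplicate {name} ids: {dupes[:5]}")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised frequencies (all-zero samples stay zero)."""
        sums = self.sample_sums().astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self, counts=self.counts[:, idx].copy(), sample_ids=list(sample_ids)
        )

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return replace(
            self, counts=self.counts[idx, :].copy(), taxon_ids=list(taxon_ids)
        )

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.taxon_sums() > 0
        return replace(
            self,
            counts=self.counts[keep, :].copy(),
            taxon_ids=[t for t, k in zip(self.taxon_ids, keep) if k],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


def read_count_table(
    path,
    orientation_hint: Literal["taxa_rows", "samples_rows", None] = None,
    kingdom: Kingdom = "bacteria",
) -> CountTable:
    """Read a TSV count table; first column holds row ids.

    Orientation is forced by ``orientation_hint`` or auto-detected: the
    larger dimension is taken to be taxa (ties resolve to taxa-as-rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise SchemaError(f"empty count table: {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric cell in count table {path}: {exc}") from None
    if orientation_hint == "samples_rows" or (
        orientation_hint is None and df.shape[1] > df.shape[0]
    ):
        df = df.T
        values = values.T
    return CountTable(
        counts=values,
        taxon_ids=list(df.index),
        sample_ids=list(df.columns),
        kingdom=kingdom,
    )


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


def filter_low_count(table: CountTable, min_total: int = 20) -> CountTable:
    """Retain taxa whose total read count is strictly greater than ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.taxon_sums() > min_total
    if not keep.any():
        raise ValueError(
            f"filter_low_count removed all {table.n_taxa} taxa "
            f"(max row sum {table.taxon_sums().max()}, min_total {min_total})"
        )
    return replace(
        table,
        counts=table.counts[keep, :].copy(),
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
    )


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged)
    rather than rejected — the common practice when a fixed rarefaction
    depth is applied across a study.  The draw per sample is multivariate
    hypergeometric, i.e. an exact without-replacement subsample.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        log.warning("rarefy: dropping %d under-depth samples: %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    cols = []
    for j in np.flatnonzero(keep):
        cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
    return replace(
        table,
        counts=np.column_stack(cols).astype(np.int64),
        sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
    )


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """taxon_id -> seven-rank lineage (missing ranks empty strings)."""

    table: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.table.columns]
        if missing:
            raise SchemaError(f"taxonomy missing rank columns: {missing}")
        if self.table.index.duplicated().any():
            raise SchemaError("duplicate taxon ids in taxonomy")
        self.table = self.table[list(RANKS)].fillna("").astype(str)

    def rank(self, taxon_id: str, rank: str) -> str:
        return str(self.table.at[taxon_id, rank])

    def ranks_for(self, taxon_ids: Iterable[str], rank: str) -> pd.Series:
        return self.table.loc[list(taxon_ids), rank]


def _strip_rank_prefix(value: str) -> str:
    v = value.strip()
    for pref in _RANK_PREFIXES:
        if v.startswith(pref):
            return v[len(pref):]
    return v


def read_taxonomy(path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for r in RANKS:
        if r in df.columns:
            df[r] = df[r].map(_strip_rank_prefix)
        else:
            df[r] = ""
    return Taxonomy(df)


def write_taxonomy(tax: Taxonomy, path) -> None:
    tax.table.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SOIL_VARS = ("pH", "AP", "moisture", "DOC", "NH4_N", "NO3_N")
_META_REQUIRED = ("cultivar", "resistance", "fertilization", "replicate", "yield")

#: CS/CR/FS/FR labels derive from fertilization x resistance.
_GROUP_CODE = {
    ("control", "susceptible"): "CS",
    ("control", "resistant"): "CR",
    ("fertilized", "susceptible"): "FS",
    ("fertilized", "resistant"): "FR",
}


@dataclass
class SampleMetadata:
    table: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        missing = [c for c in _META_REQUIRED + SOIL_VARS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"metadata missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise SchemaError("duplicate sample ids in metadata")
        bad_res = set(self.table["resistance"]) - {"resistant", "susceptible"}
        if bad_res:
            raise SchemaError(f"unknown resistance values: {bad_res}")
        bad_fert = set(self.table["fertilization"]) - {"control", "fertilized"}
        if bad_fert:
            raise SchemaError(f"unknown fertilization values: {bad_fert}")
        if (self.table["yield"].astype(float) < 0).any():
            raise SchemaError("negative yield values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_labels(self) -> pd.Series:
        """CS / CR / FS / FR per sample."""
        return pd.Series(
            [
                _GROUP_CODE[(f, r)]
                for f, r in zip(self.table["fertilization"], self.table["resistance"])
            ],
            index=self.table.index,
            name="group",
        )

    def samples_in_class(self, resistance: str) -> list[str]:
        return list(self.table.index[self.table["resistance"] == resistance])

    def soil_matrix(self) -> np.ndarray:
        return self.table[list(SOIL_VARS)].to_numpy(dtype=float)

    def yields(self) -> np.ndarray:
        return self.table["yield"].to_numpy(dtype=float)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Rooted tree with non-negative branch lengths; tips named by taxon id."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise SchemaError("negative branch length in tree")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def patristic_matrix(self, taxon_ids: Sequence[str] | None = None) -> np.ndarray:
        """Symmetric tip-to-tip path-length matrix in ``taxon_ids`` order."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.tip_labels if taxon_ids is None else list(taxon_ids)
        ns = self.tree.taxon_namespace
        taxa = {}
        for lab in labels:
            t = ns.get_taxon(lab)
            if t is None:
                raise KeyError(f"taxon {lab!r} missing from tree")
            taxa[lab] = t
        n = len(labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
        return d

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick")


def read_tree(path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return PhyloTree(tree)


def tree_from_newick(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Beneficial-taxa list
# ---------------------------------------------------------------------------


@dataclass
class BeneficialList:
    """Taxonomy keys (at ``rank``) flagged as potentially plant-beneficial.

    Matching is case-insensitive exact string comparison at the configured
    rank; entries are stored lower-cased.
    """

    entries: frozenset[str]
    rank: str = "genus"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise SchemaError(f"unknown rank {self.rank!r}")
        entries = frozenset(str(e).strip().lower() for e in self.entries if str(e).strip())
        if not entries:
            raise SchemaError("beneficial list is empty")
        self.entries = entries

    def match_taxa(self, taxonomy: Taxonomy, taxon_ids: Sequence[str]) -> set[str]:
        """Taxon ids whose taxonomy at ``rank`` appears in the list."""
        names = taxonomy.ranks_for(taxon_ids, self.rank).str.strip().str.lower()
        return set(names.index[names.isin(self.entries)])


def read_beneficial(path, rank: str = "genus") -> BeneficialList:
    df = pd.read_csv(path, sep="\t", dtype=str)
    col = df.columns[0]
    return BeneficialList(frozenset(df[col].dropna().map(_strip_rank_prefix)), rank=rank)


def write_beneficial(ben: BeneficialList, path) -> None:
    pd.DataFrame({ben.rank: sorted(ben.entries)}).to_csv(path, sep="\t", index=False)
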