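"""Synthetic study generator with known ground truth.

Emulates the data structure of a field phyllosphere study: 10 sorghum
cultivars (5 resistant to nutrient deficiency, 5 susceptible) x 2
fertilization treatments x 3 replicates = 60 leaf samples, with an OTU
count table per kingdom, a rooted phylogeny, 7-rank taxonomy, sample
metadata (yield + 6 soil variables) and a beneficial-genus list.

Four count generators plant the signals the pipeline is designed to
detect:

* ``gen_neutral_counts``   — Sloan-style neutral sampling: metacommunity
  relative abundances p (lognormal), per-sample composition
  Dirichlet(N*m*p), reads multinomial.  Ground-truth migration rate m.
* ``gen_selected_counts``  — adds phylogenetic habitat filtering: habitat
  optima evolve by Brownian motion on the tree and group-specific
  environments re-weight taxa by exp(-s * (optimum - env)^2).  s = 0
  reduces bit-for-bit to the neutral generator at the same seed.
* ``gen_correlated_abundances`` — planted modular correlation structure:
  one latent factor per module, hub taxa loading ~1 on their factor,
  regular members loading ``within_module_corr`` (so member-member
  correlation is its square); latent log-abundances exponentiated and
  multinomially sampled.
* ``gen_metadata_yield``   — soil chemistry from a fixed multivariate
  normal; yield = b_soil * soilPC1 + b_kbs(class) * KBS + noise with the
  KBS coefficient switching sign between resistant and susceptible
  cultivars.

``generate_study`` assembles a complete bundle; one module of the
bacterial table is habitat-restricted (its factor is boosted in a small
sample subset) so that its hub taxa are simultaneously keystone,
specialist and — via the emitted beneficial list — KBS ground truth.

Every generator is a pure function of (spec, seed): per-stage seeds
derive deterministically from the master seed.
"""

from __future__ import annotations

import random as _pyrandom
import zlib
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io_core import (
    RANKS,
    SOIL_VARS,
    BeneficialList,
    CountTable,
    PhyloTree,
    SampleMetadata,
    Taxonomy,
    write_beneficial,
    write_count_table,
    write_metadata,
    write_taxonomy,
)
from .sem import soil_pc1

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "StudyBundle",
    "stage_rng",
    "gen_tree",
    "gen_neutral_counts",
    "gen_selected_counts",
    "gen_correlated_abundances",
    "gen_metadata_yield",
    "design_frame",
    "generate_study",
    "write_bundle",
]


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass
class YieldCoefficients:
    """Standardised-scale path coefficients for the planted yield model."""

    b_soil: float = 0.5
    b_kbs_resistant: float = 0.8
    b_kbs_susceptible: float = -0.8
    noise_sd: float = 0.5


@dataclass
class SynthSpec:
    """Ground-truth parameters of one synthetic kingdom.

    Defaults reproduce the study design (60 samples) at a desk-scale
    community size: 400 taxa, 2000 reads/sample, migration rate 0.10.
    """

    n_taxa: int = 400
    n_cultivars: int = 10
    n_resistant: int = 5
    n_replicates: int = 3
    migration_m: float = 0.10
    reads_per_sample: int = 2000
    meta_mu: float = 0.0
    meta_sigma: float = 2.0
    selection_strength: float = 0.0
    n_modules: int = 4
    module_size: int = 25
    within_module_corr: float = 0.75
    n_hubs_per_module: int = 1
    latent_sd: float = 1.0
    background_latent_sd: float = 0.3
    module_total_share: float = 0.25
    beneficial_fraction: float = 0.10
    restricted_n_samples: int = 8
    restricted_boost: float = 2.0
    yield_coefficients: YieldCoefficients = field(default_factory=YieldCoefficients)
    kingdom: str = "bacteria"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.migration_m <= 1.0):
            raise ValueError("migration_m must be in (0, 1]")
        if not (0.0 <= self.within_module_corr < 1.0):
            raise ValueError("within_module_corr must be in [0, 1)")
        if not (0.0 <= self.beneficial_fraction <= 1.0):
            raise ValueError("beneficial_fraction must be in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.n_modules * self.module_size > self.n_taxa:
            raise ValueError("module taxa exceed n_taxa")
        if not (0 < self.n_resistant < self.n_cultivars):
            raise ValueError("need both resistant and susceptible cultivars")

    @property
    def n_samples(self) -> int:
        return self.n_cultivars * 2 * self.n_replicates

    @property
    def n_samples_per_group(self) -> int:
        # CS/CR/FS/FR are balanced only when resistant == susceptible cultivars
        return self.n_resistant * self.n_replicates

    def taxon_ids(self) -> list[str]:
        tag = "b" if self.kingdom == "bacteria" else "f"
        return [f"OTU{tag}_{i:04d}" for i in range(self.n_taxa)]


@dataclass
class GroundTruth:
    migration_m: float
    metacommunity_p: np.ndarray
    niche_labels: dict[str, str]
    module_of_taxon: dict[str, int]
    hub_ids: list[str]
    beneficial_genera: set[str]
    kbs_taxa: list[str]
    yield_coefficients: YieldCoefficients
    habitat_optima: dict[str, float] | None = None
    restricted_samples: list[str] | None = None


@dataclass
class StudyBundle:
    bacteria: CountTable
    fungi: CountTable
    taxonomy: Taxonomy
    tree_bacteria: PhyloTree
    tree_fungi: PhyloTree
    metadata: SampleMetadata
    beneficial: BeneficialList
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------


def design_frame(spec: SynthSpec) -> pd.DataFrame:
    """Sample design: cultivar, resistance class, fertilization, replicate."""
    rows = []
    for c in range(spec.n_cultivars):
        resistance = "resistant" if c < spec.n_resistant else "susceptible"
        for fert in ("control", "fertilized"):
            for rep in range(1, spec.n_replicates + 1):
                sid = f"c{c + 1:02d}_{fert[0].upper()}_r{rep}"
                rows.append(
                    {
                        "sample_id": sid,
                        "cultivar": f"cv{c + 1:02d}",
                        "resistance": resistance,
                        "fertilization": fert,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


def gen_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) random ultrametric tree, depth scaled to 1."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_pyrandom.Random(int(seed)),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth <= 0:
        raise RuntimeError("degenerate simulated tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    # relabel tips in leaf-iteration order to the canonical taxon ids
    tag_ids = [f"OTUb_{i:04d}" for i in range(n_taxa)]
    for leaf, tid in zip(tree.leaf_node_iter(), tag_ids):
        leaf.taxon.label = tid
    return PhyloTree(tree)


def _relabel_tree(tree: PhyloTree, taxon_ids: list[str]) -> PhyloTree:
    leaves = list(tree.tree.leaf_node_iter())
    if len(leaves) != len(taxon_ids):
        raise ValueError("tip count mismatch")
    for leaf, tid in zip(leaves, taxon_ids):
        leaf.taxon.label = tid
    return tree


# ---------------------------------------------------------------------------
# Neutral / selected count generation
# ---------------------------------------------------------------------------


def _metacommunity(spec: SynthSpec) -> np.ndarray:
    rng = stage_rng(spec.seed, f"meta:{spec.kingdom}")
    raw = rng.lognormal(spec.meta_mu, spec.meta_sigma, size=spec.n_taxa)
    return raw / raw.sum()


def _sample_counts(
    spec: SynthSpec, group_p: np.ndarray, group_index: np.ndarray
) -> np.ndarray:
    """Dirichlet-multinomial draw per sample.

    ``group_p``: (n_groups, n_taxa) source pools; ``group_index``: pool per
    sample.  Concentration N*m*p is the stationary approximation of the
    neutral birth-death immigration process the NCM fit assumes.
    """
    rng = stage_rng(spec.seed, f"counts:{spec.kingdom}")
    n = spec.reads_per_sample
    cols = np.empty((spec.n_taxa, len(group_index)), dtype=np.int64)
    for j, g in enumerate(group_index):
        alpha = n * spec.migration_m * group_p[g]
        # gamma representation tolerates the many near-zero concentrations
        gam = rng.gamma(np.maximum(alpha, 1e-12))
        total = gam.sum()
        if total <= 0:  # pragma: no cover - essentially impossible
            gam[:] = group_p[g]
            total = gam.sum()
        cols[:, j] = rng.multinomial(n, gam / total)
    return cols


def gen_neutral_counts(spec: SynthSpec) -> CountTable:
    """Neutral-sampling count table; ground-truth m = ``spec.migration_m``."""
    p = _metacommunity(spec)
    design = design_frame(spec)
    group_index = np.zeros(len(design), dtype=int)
    counts = _sample_counts(spec, (p / p.sum())[None, :], group_index)
    return CountTable(counts, spec.taxon_ids(), list(design.index), spec.kingdom)


def brownian_trait(tree: PhyloTree, seed: int, sigma: float = 1.0) -> dict[str, float]:
    """Simulate a Brownian-motion trait along the tree; returns tip values."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    root = tree.tree.seed_node
    values[id(root)] = 0.0
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length or 0.0
        values[id(node)] = values[id(node.parent_node)] + rng.normal(
            0.0, sigma * np.sqrt(max(bl, 0.0))
        )
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.tree.leaf_node_iter()
    }


def gen_selected_counts(spec: SynthSpec, tree: PhyloTree) -> CountTable:
    """Counts under phylogenetic habitat selection between cultivar classes.

    Habitat optima are Brownian on the tree (phylogenetically
    autocorrelated, the condition the nearest-taxon index detects);
    resistant samples draw from environment +1, susceptible from -1, with
    taxon weights p_i * exp(-s * (h_i - e)^2).
    """
    p = _metacommunity(spec)
    taxon_ids = spec.taxon_ids()
    design = design_frame(spec)
    s = spec.selection_strength
    if s > 0:
        hab_rng = stage_rng(spec.seed, f"habitat:{spec.kingdom}")
        trait = brownian_trait(tree, int(hab_rng.integers(2**31 - 1)))
        h = np.array([trait[t] for t in taxon_ids])
        h = (h - h.mean()) / (h.std() or 1.0)
    else:
        h = np.zeros(spec.n_taxa)
    envs = np.array([1.0, -1.0])  # resistant, susceptible
    group_p = np.empty((2, spec.n_taxa))
    for g, e in enumerate(envs):
        w = p * np.exp(-s * (h - e) ** 2)
        group_p[g] = w / w.sum()
    group_index = (design["resistance"] == "susceptible").to_numpy().astype(int)
    counts = _sample_counts(spec, group_p, group_index)
    return CountTable(counts, taxon_ids, list(design.index), spec.kingdom)


# ---------------------------------------------------------------------------
# Correlated (modular) count generation
# ---------------------------------------------------------------------------


def _module_assignment(spec: SynthSpec):
    """First block of taxa become module members, hubs first within each."""
    module_of = np.full(spec.n_taxa, -1, dtype=int)
    hub_mask = np.zeros(spec.n_taxa, dtype=bool)
    for m in range(spec.n_modules):
        idx = np.arange(m * spec.module_size, (m + 1) * spec.module_size)
        module_of[idx] = m
        hub_mask[idx[: spec.n_hubs_per_module]] = True
    return module_of, hub_mask


def _module_correlation(spec: SynthSpec) -> np.ndarray:
    """Within-module correlation block (hubs first); must be PD."""
    k = spec.module_size
    load = np.full(k, spec.within_module_corr)
    load[: spec.n_hubs_per_module] = 0.995  # hubs track the module factor
    corr = np.outer(load, load)
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("planted module covariance is not positive definite")
    return corr


def gen_correlated_abundances(
    spec: SynthSpec, restricted_module: int | None = None
):
    """Counts with planted modules and hub taxa.

    Returns ``(table, module_of_taxon, hub_ids, restricted_samples)``.
    If ``restricted_module`` is given, that module's latent factor is
    boosted by ``spec.restricted_boost`` in ``spec.restricted_n_samples``
    resistant samples and suppressed elsewhere, making its taxa habitat
    specialists while keeping their within-module co-fluctuation.

    Module taxa share ``module_total_share`` of the metacommunity (evenly
    lognormal within, so their ranks resolve at realistic read depths
    without dominating the composition); background taxa carry mild
    independent latent noise (``background_latent_sd``) so their sample
    spread stays near the multinomial fixed-margin expectation.
    """
    taxon_ids = spec.taxon_ids()
    design = design_frame(spec)
    n_samples = len(design)
    module_of, hub_mask = _module_assignment(spec)
    n_module_taxa = spec.n_modules * spec.module_size
    corr = _module_correlation(spec)
    chol = np.linalg.cholesky(corr)

    rng = stage_rng(spec.seed, f"corrlatent:{spec.kingdom}")
    p = np.empty(spec.n_taxa)
    base_mod = rng.lognormal(0.0, 0.5, size=n_module_taxa)
    p[:n_module_taxa] = spec.module_total_share * base_mod / base_mod.sum()
    base_bg = rng.lognormal(spec.meta_mu, spec.meta_sigma, size=spec.n_taxa - n_module_taxa)
    p[n_module_taxa:] = (1 - spec.module_total_share) * base_bg / base_bg.sum()

    z = spec.background_latent_sd * rng.standard_normal((spec.n_taxa, n_samples))
    for m in range(spec.n_modules):
        idx = np.flatnonzero(module_of == m)
        z[idx, :] = spec.latent_sd * (
            chol @ rng.standard_normal((spec.module_size, n_samples))
        )

    restricted_samples: list[str] = []
    if restricted_module is not None:
        res_idx = np.flatnonzero((design["resistance"] == "resistant").to_numpy())
        pick = rng.choice(res_idx, size=spec.restricted_n_samples, replace=False)
        restricted_samples = [design.index[i] for i in sorted(pick)]
        offset = np.full(n_samples, -spec.restricted_boost)
        offset[pick] = spec.restricted_boost
        idx = np.flatnonzero(module_of == restricted_module)
        z[idx, :] += offset[None, :]

    weights = p[:, None] * np.exp(z)
    weights /= weights.sum(axis=0)
    count_rng = stage_rng(spec.seed, f"corrcounts:{spec.kingdom}")
    counts = np.column_stack(
        [
            count_rng.multinomial(spec.reads_per_sample, weights[:, j])
            for j in range(n_samples)
        ]
    )
    table = CountTable(counts, taxon_ids, list(design.index), spec.kingdom)
    module_of_taxon = {
        t: int(m) for t, m in zip(taxon_ids, module_of) if m >= 0
    }
    hub_ids = [t for t, h in zip(taxon_ids, hub_mask) if h]
    return table, module_of_taxon, hub_ids, restricted_samples


# ---------------------------------------------------------------------------
# Metadata: soil chemistry + yield
# ---------------------------------------------------------------------------

#: Means of the six soil variables (pH, AP mg/kg, moisture %, DOC mg/kg,
#: NH4-N mg/kg, NO3-N mg/kg) and their standard deviations.
_SOIL_MEAN = np.array([6.5, 15.0, 20.0, 200.0, 10.0, 20.0])
_SOIL_SD = np.array([0.3, 5.0, 5.0, 50.0, 3.0, 6.0])
#: Mild positive coupling among nutrient pools; pH nearly independent.
_SOIL_CORR = np.array(
    [
        [1.0, 0.1, 0.0, 0.1, 0.0, 0.0],
        [0.1, 1.0, 0.2, 0.4, 0.3, 0.3],
        [0.0, 0.2, 1.0, 0.3, 0.2, 0.1],
        [0.1, 0.4, 0.3, 1.0, 0.4, 0.3],
        [0.0, 0.3, 0.2, 0.4, 1.0, 0.4],
        [0.0, 0.3, 0.1, 0.3, 0.4, 1.0],
    ]
)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def gen_metadata_yield(
    spec: SynthSpec, kbs_abundance: np.ndarray, design: pd.DataFrame | None = None
) -> SampleMetadata:
    """Soil vectors plus yield coupled to soil PC1 and KBS abundance.

    yield_raw = b_soil*z(PC1) + b_kbs(class)*z_class(KBS) + noise, mapped
    affinely to a plausible grain-yield scale (t/ha) and globally shifted
    to be non-negative.  KBS is z-scored within each resistance class so
    the planted coefficient is the within-class standardized effect.
    """
    if design is None:
        design = design_frame(spec)
    kbs_abundance = np.asarray(kbs_abundance, dtype=float)
    if kbs_abundance.shape[0] != len(design):
        raise ValueError("kbs_abundance length must match sample count")
    rng = stage_rng(spec.seed, "soil-yield")
    cov = _SOIL_CORR * np.outer(_SOIL_SD, _SOIL_SD)
    soil = rng.multivariate_normal(_SOIL_MEAN, cov, size=len(design))
    pc1 = soil_pc1(soil)

    yc = spec.yield_coefficients
    resistant = (design["resistance"] == "resistant").to_numpy()
    kbs_z = np.empty(len(design))
    kbs_z[resistant] = _zscore(kbs_abundance[resistant])
    kbs_z[~resistant] = _zscore(kbs_abundance[~resistant])
    b_kbs = np.where(resistant, yc.b_kbs_resistant, yc.b_kbs_susceptible)
    raw = (
        yc.b_soil * _zscore(pc1)
        + b_kbs * kbs_z
        + yc.noise_sd * rng.standard_normal(len(design))
    )
    yields = 8.0 + 2.0 * raw  # t/ha scale
    if yields.min() < 0:
        yields = yields - yields.min()

    meta = design.copy()
    meta["yield"] = yields
    for k, name in enumerate(SOIL_VARS):
        meta[name] = soil[:, k]
    return SampleMetadata(meta)


# ---------------------------------------------------------------------------
# Taxonomy + beneficial list
# ---------------------------------------------------------------------------

_BACT_CLASSES = [
    ("Firmicutes", "Bacilli"),
    ("Bacteroidetes", "Bacteroidia"),
    ("Proteobacteria", "Alphaproteobacteria"),
    ("Proteobacteria", "Gammaproteobacteria"),
    ("Actinobacteria", "Actinomycetia"),
    ("Planctomycetota", "Planctomycetia"),
    ("Verrucomicrobia", "Verrucomicrobiae"),
    ("Chloroflexi", "Chloroflexia"),
]
_FUNG_CLASSES = [
    ("Ascomycota", "Sordariomycetes"),
    ("Ascomycota", "Dothideomycetes"),
    ("Basidiomycota", "Agaricomycetes"),
    ("Basidiomycota", "Tremellomycetes"),
]


def _gen_taxonomy(spec: SynthSpec) -> pd.DataFrame:
    rng = stage_rng(spec.seed, f"taxonomy:{spec.kingdom}")
    if spec.kingdom == "bacteria":
        pool, domain, tag = _BACT_CLASSES, "Bacteria", "Bact"
    else:
        pool, domain, tag = _FUNG_CLASSES, "Fungi", "Fung"
    picks = rng.integers(len(pool), size=spec.n_taxa)
    rows = []
    for i, (tid, k) in enumerate(zip(spec.taxon_ids(), picks)):
        phylum, cls = pool[k]
        rows.append(
            {
                "taxon_id": tid,
                "domain": domain,
                "phylum": phylum,
                "class": cls,
                "order": f"{tag}Order{k:02d}",
                "family": f"{tag}Family{i % 40:02d}",
                "genus": f"{tag}Genus{i:04d}",
                "species": "",
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def generate_study(
    spec: SynthSpec, spec_fungi: SynthSpec | None = None
) -> StudyBundle:
    """Complete synthetic study with planted KBS ground truth.

    Bacteria carry the planted modular correlation structure; module 0 is
    habitat-restricted, making its taxa specialists, and its hub taxa are
    flagged beneficial — the planted KBS.  Fungi are an independent,
    smaller neutral community (supporting cross-kingdom edge accounting
    without further planted structure).  Yield is coupled to the realised
    per-sample KBS relative abundance.
    """
    if spec.kingdom != "bacteria":
        raise ValueError("primary spec must be the bacterial kingdom")
    if spec_fungi is None:
        n_f = max(spec.n_taxa // 2, 50)
        spec_fungi = _dc_replace(
            spec,
            kingdom="fungi",
            n_taxa=n_f,
            seed=spec.seed + 1,
            n_modules=2,
            module_size=min(spec.module_size, n_f // 4),
        )

    bacteria, module_of, hub_ids, restricted = gen_correlated_abundances(
        spec, restricted_module=0
    )
    fungi = gen_neutral_counts(spec_fungi)

    tree_b = _relabel_tree(gen_tree(spec.n_taxa, spec.seed + 11), spec.taxon_ids())
    tree_f = _relabel_tree(
        gen_tree(spec_fungi.n_taxa, spec_fungi.seed + 11), spec_fungi.taxon_ids()
    )

    tax_b = _gen_taxonomy(spec)
    tax_f = _gen_taxonomy(spec_fungi)
    taxonomy = Taxonomy(pd.concat([tax_b, tax_f]))

    # planted KBS: hubs of the restricted module (specialist by
    # construction) and of one free module (keystone by construction)
    kbs_taxa = [t for t in hub_ids if module_of[t] in (0, 1)]
    kbs_genera = {taxonomy.rank(t, "genus").lower() for t in kbs_taxa}
    ben_rng = stage_rng(spec.seed, "beneficial")
    all_genera = [g.lower() for g in tax_b["genus"]]
    n_extra = max(int(spec.beneficial_fraction * len(all_genera)) - len(kbs_genera), 0)
    extra = set(ben_rng.choice(all_genera, size=n_extra, replace=False))
    beneficial = BeneficialList(frozenset(kbs_genera | extra), rank="genus")

    kbs_idx = [spec.taxon_ids().index(t) for t in kbs_taxa]
    kbs_abund = bacteria.relative_abundance()[kbs_idx, :].sum(axis=0)
    metadata = gen_metadata_yield(spec, kbs_abund)

    niche_labels = {
        t: ("specialist" if m == 0 else "unplanted") for t, m in module_of.items()
    }
    truth = GroundTruth(
        migration_m=spec.migration_m,
        metacommunity_p=_metacommunity(spec),
        niche_labels=niche_labels,
        module_of_taxon=module_of,
        hub_ids=hub_ids,
        beneficial_genera=set(beneficial.entries),
        kbs_taxa=kbs_taxa,
        yield_coefficients=spec.yield_coefficients,
        restricted_samples=restricted,
    )
    return StudyBundle(
        bacteria=bacteria,
        fungi=fungi,
        taxonomy=taxonomy,
        tree_bacteria=tree_b,
        tree_fungi=tree_f,
        metadata=metadata,
        beneficial=beneficial,
        truth=truth,
    )


def write_bundle(bundle: StudyBundle, out_dir) -> dict[str, str]:
    """Write the bundle as the TSV/newick files io_core reads back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bacteria": out / "counts_bacteria.tsv",
        "fungi": out / "counts_fungi.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree_bacteria": out / "tree_bacteria.nwk",
        "tree_fungi": out / "tree_fungi.nwk",
        "metadata": out / "metadata.tsv",
        "beneficial": out / "beneficial.tsv",
    }
    write_count_table(bundle.bacteria, paths["bacteria"])
    write_count_table(bundle.fungi, paths["fungi"])
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    bundle.tree_bacteria.write(paths["tree_bacteria"])
    bundle.tree_fungi.write(paths["tree_fungi"])
    write_metadata(bundle.metadata, paths["metadata"])
    write_beneficial(bundle.beneficial, paths["beneficial"])
    return {k: str(v) for k, v in paths.items()}
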