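"""Signed Spearman co-occurrence networks with Zi-Pi keystone roles.

Edges are pairwise Spearman correlations (mid-ranks for ties, p from the
t approximation) passing |rho| > 0.6 and p < 0.01 — raw p-values, as is
conventional for this network construction (an optional Benjamini-
Hochberg flag exists).  Modules come from seeded Louvain modularity
maximisation; node roles follow the within-module degree z-score Zi and
participation coefficient Pi with the standard cutoffs Zi > 2.5 (module
hub) and Pi > 0.62 (connector); nodes meeting both are network hubs, and
all non-peripheral nodes are keystone taxa.

The "keystone score" sqrt((Zi/2.5)^2 + (Pi/0.62)^2) is a normalised
distance past the role cutoffs — a package-defined proxy for ranking
keystones, labelled as such in outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import CountTable

log = logging.getLogger("phyllokbs")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
MIN_MODULE_SIZE = 3

ROLES = ("peripheral", "module_hub", "connector", "network_hub")


@dataclass
class CoNetwork:
    graph: nx.Graph
    nodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    rho_min: float = 0.6
    p_max: float = 0.01

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def keystone_taxa(self) -> set[str]:
        if "role" not in self.nodes.columns:
            raise RuntimeError("run detect_modules + zi_pi before querying keystones")
        return set(self.nodes.index[self.nodes["role"] != "peripheral"])


def _spearman_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho (mid-ranks) and two-sided t-approximation p.

    ``x``: taxa-by-samples.  Rows must be non-constant.
    """
    n = x.shape[1]
    ranks = sps.rankdata(x, axis=1)
    rz = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((rz**2).sum(axis=1))
    rho = (rz @ rz.T) / np.outer(norm, norm)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1
    return rho, p


def build_network(
    tables: list[CountTable] | CountTable,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    prevalence_min: float = 0.2,
    fdr: bool = False,
    niche_labels: pd.Series | None = None,
) -> CoNetwork:
    """Merged cross-kingdom co-occurrence network for one sample set.

    Each kingdom's table is converted to relative abundance before
    merging; taxa present in fewer than ``prevalence_min`` of the samples
    are excluded, constant vectors are skipped with a log message, and
    isolated nodes are dropped from the final graph.
    """
    if isinstance(tables, CountTable):
        tables = [tables]
    sample_ids = tables[0].sample_ids
    if any(t.sample_ids != sample_ids for t in tables[1:]):
        raise ValueError("all tables must share the same sample set and order")
    if len(sample_ids) < 4:
        raise ValueError("need >= 4 samples to build a correlation network")

    rows, taxon_ids, kingdoms, rel_ab = [], [], [], []
    for t in tables:
        rel = t.relative_abundance()
        prev = (t.counts > 0).mean(axis=1)
        for i, tid in enumerate(t.taxon_ids):
            if prev[i] < prevalence_min:
                continue
            if np.ptp(rel[i]) == 0:
                log.info("build_network: skipping constant taxon %s", tid)
                continue
            rows.append(rel[i])
            taxon_ids.append(tid)
            kingdoms.append(t.kingdom)
            rel_ab.append(rel[i].mean())
    if len(rows) < 2:
        raise ValueError("fewer than 2 taxa pass the prevalence filter")
    x = np.vstack(rows)
    rho, p = _spearman_matrix(x)

    iu = np.triu_indices(len(taxon_ids), k=1)
    rho_u, p_u = rho[iu], p[iu]
    if fdr:
        order = np.argsort(p_u)
        m = len(p_u)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p_u[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p_u = np.minimum(adj, 1.0)
    passing = (np.abs(rho_u) > rho_min) & (p_u < p_max)

    g = nx.Graph()
    edge_rows = []
    for k in np.flatnonzero(passing):
        i, j = iu[0][k], iu[1][k]
        a, b = taxon_ids[i], taxon_ids[j]
        sign = "positive" if rho_u[k] > 0 else "negative"
        pair = "".join(sorted(kingdoms[i][0].upper() + kingdoms[j][0].upper()))
        g.add_edge(a, b, rho=float(rho_u[k]), p=float(p_u[k]), sign=sign, kingdom_pair=pair)
        edge_rows.append(
            {"taxon_a": a, "taxon_b": b, "rho": float(rho_u[k]), "p": float(p_u[k]),
             "sign": sign, "kingdom_pair": pair}
        )

    info = pd.DataFrame(
        {"kingdom": kingdoms, "relative_abundance": rel_ab}, index=taxon_ids
    )
    node_df = info.loc[[t for t in taxon_ids if g.has_node(t)]].copy()
    node_df["degree"] = [g.degree(t) for t in node_df.index]
    if niche_labels is not None:
        node_df["niche_label"] = niche_labels.reindex(node_df.index)
    for t in node_df.index:
        g.nodes[t].update(node_df.loc[t].to_dict())
    return CoNetwork(g, node_df, pd.DataFrame(edge_rows), rho_min, p_max)


def topology(net: CoNetwork) -> dict:
    """Node/edge counts, average degree, betweenness, edge-type proportions."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    betweenness = nx.betweenness_centrality(g, normalized=False)
    net.nodes["betweenness"] = pd.Series(betweenness).reindex(net.nodes.index)
    edge_types = {}
    if e and not net.edges.empty:
        combos = net.edges.groupby(["kingdom_pair", "sign"]).size()
        edge_types = {f"{k[0]}_{k[1]}": v / e for k, v in combos.items()}
    return {
        "n_nodes": n,
        "n_edges": e,
        "avg_degree": 2 * e / n if n else 0.0,
        "betweenness": betweenness,
        "edge_type_proportions": edge_types,
    }


def detect_modules(net: CoNetwork, seed: int = 0) -> pd.Series:
    """Seeded Louvain modules on the unweighted graph.

    Modules smaller than 3 nodes are merged into a single "rest" pool
    (module id -1) excluded from Zi standardisation.
    """
    communities = nx.community.louvain_communities(net.graph, weight=None, seed=seed)
    communities = sorted(communities, key=len, reverse=True)
    module = {}
    next_id = 0
    for comm in communities:
        if len(comm) >= MIN_MODULE_SIZE:
            for node in comm:
                module[node] = next_id
            next_id += 1
        else:
            for node in comm:
                module[node] = -1
    s = pd.Series(module, name="module").reindex(net.nodes.index)
    net.nodes["module"] = s
    return s


def zi_pi(net: CoNetwork) -> pd.DataFrame:
    """Within-module degree z-score, participation coefficient and role."""
    if "module" not in net.nodes.columns:
        detect_modules(net)
    g = net.graph
    module = net.nodes["module"]
    # within-module degree per node
    k_within = {}
    k_by_module = {}
    for node in net.nodes.index:
        neigh_modules = pd.Series([module[v] for v in g.neighbors(node)])
        counts = neigh_modules.value_counts()
        k_by_module[node] = counts
        k_within[node] = int(counts.get(module[node], 0))
    zi = pd.Series(0.0, index=net.nodes.index)
    for mod in module.unique():
        if mod == -1:
            continue  # rest pool excluded from standardisation
        members = module.index[module == mod]
        vals = np.array([k_within[n] for n in members], dtype=float)
        sd = vals.std(ddof=0)
        if sd > 0:
            zi.loc[members] = (vals - vals.mean()) / sd
    pi = pd.Series(0.0, index=net.nodes.index)
    for node in net.nodes.index:
        k = g.degree(node)
        if k == 0:
            continue
        shares = (k_by_module[node] / k) ** 2
        pi[node] = 1.0 - float(shares.sum())
    role = np.where(
        (zi > ZI_THRESHOLD) & (pi > PI_THRESHOLD), "network_hub",
        np.where(zi > ZI_THRESHOLD, "module_hub",
                 np.where(pi > PI_THRESHOLD, "connector", "peripheral")),
    )
    net.nodes["zi"] = zi
    net.nodes["pi"] = pi
    net.nodes["role"] = role
    net.nodes["keystone"] = net.nodes["role"] != "peripheral"
    return net.nodes[["zi", "pi", "role", "keystone"]]


def keystone_scores(net: CoNetwork) -> pd.DataFrame:
    """Proxy keystone score and its correlations with network metrics.

    score = sqrt((Zi/2.5)^2 + (Pi/0.62)^2); Pearson r of log(score) vs
    betweenness and vs degree over keystone nodes (where score >= 1), and
    restricted to specialist keystones when niche labels are attached.
    """
    if "role" not in net.nodes.columns:
        zi_pi(net)
    if "betweenness" not in net.nodes.columns:
        topology(net)
    nodes = net.nodes
    score = np.sqrt((nodes["zi"] / ZI_THRESHOLD) ** 2 + (nodes["pi"] / PI_THRESHOLD) ** 2)
    nodes["keystone_score"] = score

    def _corrs(sub: pd.DataFrame) -> dict:
        out = {}
        if len(sub) >= 3 and (sub["keystone_score"] > 0).all():
            ls = np.log(sub["keystone_score"])
            for metric in ("betweenness", "degree"):
                if ls.std() > 0 and sub[metric].std() > 0:
                    r, p = sps.pearsonr(ls, sub[metric])
                else:
                    r, p = np.nan, np.nan
                out[metric] = {"r": float(r), "p": float(p)}
        return out

    keystones = nodes[nodes["keystone"]]
    regressions = {"all_keystones": _corrs(keystones)}
    if "niche_label" in nodes.columns:
        spec = keystones[keystones["niche_label"] == "specialist"]
        regressions["specialist_keystones"] = _corrs(spec)
    nodes.attrs["keystone_regressions"] = regressions
    return nodes
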