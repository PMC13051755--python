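from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phyllokbs.io_core import CountTable
from phyllokbs.network import (
    CoNetwork,
    build_network,
    detect_modules,
    keystone_scores,
    topology,
    zi_pi,
)


def five_edge_fixture() -> CountTable:
    """8 taxa x 10 samples engineered so exactly 5 pairs pass the edge test.

    On the relative abundances the network correlates, exactly the pairs
    (t0,t1), (t2,t3), (t4,t5), (t4,t6), (t5,t6) satisfy |rho| > 0.6 and
    p < 0.01 (all with |rho| >= 0.72); every other pair stays below 0.5.
    """
    x = np.array(
        [
            [18, 54, 3, 56, 34, 43, 20, 58, 35, 56],
            [22, 55, 3, 56, 37, 43, 22, 59, 37, 58],
            [34, 30, 10, 37, 24, 41, 17, 33, 22, 23],
            [71, 61, 20, 75, 48, 84, 37, 66, 44, 49],
            [2, 37, 56, 9, 25, 17, 44, 28, 33, 3],
            [118, 47, 8, 104, 73, 86, 33, 64, 55, 114],
            [3, 14, 18, 30, 12, 14, 35, 42, 25, 6],
            [28, 22, 3, 16, 49, 15, 28, 44, 13, 1],
        ]
    )
    return CountTable(x, [f"t{i}" for i in range(8)], [f"s{j}" for j in range(10)])


def graph_network(g: nx.Graph) -> CoNetwork:
    """Wrap a bare graph as a CoNetwork for the topology/role operations."""
    nodes = pd.DataFrame(
        {"kingdom": "bacteria", "relative_abundance": 0.01,
         "degree": [g.degree(n) for n in g.nodes]},
        index=list(g.nodes),
    )
    return CoNetwork(g, nodes, pd.DataFrame())


class TestBuildNetwork:
    def test_monotone_pair_gets_positive_edge(self):
        # constant filler keeps the pair's relative abundances monotone
        base = np.arange(1, 11)
        counts = np.vstack([base * 10, base * 20 + 1, np.full(10, 1000)])
        t = CountTable(counts, ["a", "b", "filler"], [f"s{j}" for j in range(10)])
        net = build_network(t, prevalence_min=0.0)
        assert net.graph.has_edge("a", "b")
        assert net.graph.edges["a", "b"]["sign"] == "positive"
        assert net.graph.edges["a", "b"]["rho"] == pytest.approx(1.0)

    def test_anti_monotone_pair_negative_sign(self):
        base = np.arange(1, 11)
        counts = np.vstack([base * 10, (11 - base) * 10, np.full(10, 1000)])
        t = CountTable(counts, ["a", "b", "filler"], [f"s{j}" for j in range(10)])
        net = build_network(t, prevalence_min=0.0)
        assert net.graph.edges["a", "b"]["sign"] == "negative"
        assert net.graph.edges["a", "b"]["rho"] == pytest.approx(-1.0)

    def test_exactly_five_edges_against_hand_oracle(self):
        t = five_edge_fixture()
        x = t.relative_abundance()
        expected = set()
        for i, j in combinations(range(8), 2):  # all-pairs oracle
            rho, p = spearmanr(x[i], x[j])
            if abs(rho) > 0.6 and p < 0.01:
                expected.add((f"t{i}", f"t{j}"))
        assert len(expected) == 5
        net = build_network(t, prevalence_min=0.0)
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == {tuple(sorted(e)) for e in expected}

    def test_isolated_nodes_dropped(self):
        net = build_network(five_edge_fixture(), prevalence_min=0.0)
        assert "t7" not in net.graph

    def test_invariant_to_sample_and_taxon_ordering(self):
        t = five_edge_fixture()
        rng = np.random.default_rng(0)
        sp = rng.permutation(t.n_samples)
        tp = rng.permutation(t.n_taxa)
        shuffled = CountTable(
            t.counts[np.ix_(tp, sp)],
            [t.taxon_ids[i] for i in tp],
            [t.sample_ids[j] for j in sp],
        )
        a = build_network(t, prevalence_min=0.0)
        b = build_network(shuffled, prevalence_min=0.0)
        assert {tuple(sorted(e)) for e in a.graph.edges} == {
            tuple(sorted(e)) for e in b.graph.edges
        }

    def test_keystone_set_shrinks_as_rho_threshold_rises(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, size=(30, 20)) + 1
        counts[1] = counts[0] + rng.integers(0, 3, 20)  # correlated pair
        t = CountTable(counts, [f"t{i}" for i in range(30)], [f"s{j}" for j in range(20)])
        edges = []
        for rho_min in (0.3, 0.5, 0.7):
            try:
                net = build_network(t, rho_min=rho_min, prevalence_min=0.0)
                edges.append(net.n_edges)
            except ValueError:
                edges.append(0)
        assert edges[0] >= edges[1] >= edges[2]

    def test_too_few_samples_rejected(self):
        t = CountTable(np.ones((5, 3), dtype=int), [f"t{i}" for i in range(5)],
                       ["a", "b", "c"])
        with pytest.raises(ValueError, match="4 samples"):
            build_network(t)


class TestTopology:
    def test_triangle_graph(self):
        net = graph_network(nx.complete_graph(["a", "b", "c"]))
        topo = topology(net)
        assert topo["avg_degree"] == pytest.approx(2.0)
        assert all(v == 0 for v in topo["betweenness"].values())

    def test_path_betweenness(self):
        net = graph_network(nx.path_graph(["a", "b", "c"]))
        topo = topology(net)
        assert topo["betweenness"]["b"] == pytest.approx(1.0)

    def test_edge_type_proportions_sum_to_one(self):
        net = build_network(five_edge_fixture(), prevalence_min=0.0)
        topo = topology(net)
        assert sum(topo["edge_type_proportions"].values()) == pytest.approx(1.0)


class TestModulesAndRoles:
    def test_two_disjoint_cliques_found(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(4))
        net = graph_network(g)
        modules = detect_modules(net, seed=0)
        assert modules.nunique() == 2

    def test_planted_partition_recovery(self):
        g = nx.planted_partition_graph(4, 25, 0.3, 0.01, seed=5)
        truth = [n // 25 for n in range(100)]
        net = graph_network(g)
        modules = detect_modules(net, seed=1)
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(truth, modules[list(range(100))].tolist())
        assert ari >= 0.9

    def test_module_ids_stable_at_fixed_seed(self):
        g = nx.planted_partition_graph(3, 10, 0.6, 0.05, seed=2)
        net = graph_network(g)
        m1 = detect_modules(net, seed=3)
        net2 = graph_network(g)
        m2 = detect_modules(net2, seed=3)
        assert m1.equals(m2)

    def test_pi_closed_forms(self):
        # hub wired to 4 modules of 3 nodes each, one link per module
        g = nx.Graph()
        for m in range(4):
            g.add_edges_from([(f"m{m}a", f"m{m}b"), (f"m{m}b", f"m{m}c"), (f"m{m}a", f"m{m}c")])
            g.add_edge("hub", f"m{m}a")
        net = graph_network(g)
        detect_modules(net, seed=0)
        roles = zi_pi(net)
        assert roles.loc["hub", "pi"] == pytest.approx(1 - 4 * (1 / 16))
        assert roles.loc["hub", "role"] in ("connector", "network_hub")
        # node with all links inside its own module has participation 0
        assert roles.loc["m0b", "pi"] == pytest.approx(0.0)

    def test_zi_standardized_within_modules(self):
        g = nx.planted_partition_graph(3, 12, 0.5, 0.02, seed=7)
        net = graph_network(g)
        modules = detect_modules(net, seed=0)
        zi = zi_pi(net)["zi"]
        for m in modules.unique():
            if m == -1:
                continue
            vals = zi[modules == m]
            if vals.std(ddof=0) > 0:
                assert vals.mean() == pytest.approx(0.0, abs=1e-9)
                assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_module_hub_fraction_small_on_random_graph(self):
        g = nx.erdos_renyi_graph(300, 0.05, seed=11)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = graph_network(g)
        detect_modules(net, seed=0)
        roles = zi_pi(net)
        assert (roles["zi"] > 2.5).mean() < 0.05


class TestKeystoneScores:
    def test_score_normalisation_at_thresholds(self):
        g = nx.path_graph(["a", "b", "c"])
        net = graph_network(g)
        detect_modules(net, seed=0)
        zi_pi(net)
        net.nodes.loc["a", ["zi", "pi"]] = [2.5, 0.0]
        net.nodes.loc["b", ["zi", "pi"]] = [0.0, 0.62]
        score = np.sqrt((net.nodes["zi"] / 2.5) ** 2 + (net.nodes["pi"] / 0.62) ** 2)
        assert score["a"] == pytest.approx(1.0)
        assert score["b"] == pytest.approx(1.0)

    def test_planted_hubs_reach_top_degree_decile(self):
        from phyllokbs.synth import SynthSpec, gen_correlated_abundances

        spec = SynthSpec(seed=21, reads_per_sample=20000, within_module_corr=0.8)
        table, module_of, hubs, _ = gen_correlated_abundances(spec)
        net = build_network(table)
        deg = pd.Series({n: net.graph.degree(n) for n in net.graph})
        threshold = deg.quantile(0.9)
        assert (deg.reindex(hubs) >= threshold).all()
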