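"""Population graph, simple paths and structural metrics vs brute force."""

import itertools

import networkx as nx
import numpy as np
import pytest

from iwavesim.config import ConnectionRule, default_config
from iwavesim.graph import (
    build_population_graph,
    centralities,
    metrics_table,
    node_metrics,
    simple_paths_to_target,
)
from iwavesim.network import build_macrocolumn


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def dfs_simple_paths(graph, source, target):
    """Independent recursive enumeration of simple paths."""
    out = []

    def walk(node, visited, path):
        if node == target and len(path) > 1:
            out.append(tuple(path))
            return
        for nxt in graph.successors(node):
            if nxt not in visited:
                walk(nxt, visited | {nxt}, path + [nxt])

    walk(source, {source}, [source])
    return out


def floyd_warshall(graph, weight=None):
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b, data in graph.edges(data=True):
        d[idx[a], idx[b]] = 1.0 if weight is None else data[weight]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return nodes, d


def brute_force_centralities(graph):
    nodes, d = floyd_warshall(graph)
    n = len(nodes)
    close, harm = {}, {}
    for j, v in enumerate(nodes):
        incoming = [d[i, j] for i in range(n)
                    if i != j and np.isfinite(d[i, j])]
        close[v] = (n - 1) / sum(incoming) if incoming and sum(incoming) \
            else 0.0
        harm[v] = sum(1.0 / x for x in incoming if x > 0)
    # betweenness by explicit shortest-path enumeration
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    return close, harm, btw


def toy_graph(edges):
    g = nx.DiGraph()
    for a, b, delay, p, sign in edges:
        g.add_edge(a, b, delay=delay, p=p, log_p=float(np.log(p)),
                   sign=sign)
    return g


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

class TestBuildGraph:
    def test_default_network_has_12_nodes_with_source_afferents(
            self, default_network):
        g = build_population_graph(default_network)
        assert g.number_of_nodes() == 12
        for node in g:
            if node.endswith("_AFF"):
                assert g.in_degree(node) == 0
            if node.endswith("_BC"):
                for _, _, data in g.out_edges(node, data=True):
                    assert data["sign"] == -1

    def test_saturated_rule_gives_probability_one(self):
        cfg = default_config(n_microcolumns=2)
        cfg["rules"] = [ConnectionRule("L23_IT", "L5_PTN", 1.0, 1.0)]
        net = build_macrocolumn(cfg, seed=0)
        g = build_population_graph(net)
        assert g.edges["L23_IT", "L5_PTN"]["p"] == 1.0

    def test_empirical_probability_near_rule_probability(self):
        cfg = default_config(n_microcolumns=4)
        p = 0.4
        cfg["rules"] = [ConnectionRule("L23_IT", "L5_PTN", p, 1.0)]
        est = [
            build_population_graph(build_macrocolumn(cfg, seed=s))
            .edges["L23_IT", "L5_PTN"]["p"]
            for s in range(10)
        ]
        from scipy import stats
        lo, hi = stats.binom.interval(0.99, 10 * 64, p)
        assert lo <= np.mean(est) * 10 * 64 <= hi

    def test_edge_delay_includes_synaptic_component(self, small_network):
        g = build_population_graph(small_network)
        syn = small_network.synapses
        for a, b, data in g.edges(data=True):
            assert data["delay"] >= 0.2


# ---------------------------------------------------------------------------
# Simple paths
# ---------------------------------------------------------------------------

class TestSimplePaths:
    def test_three_node_chain_has_one_path(self):
        g = toy_graph([("A", "B", 1.0, 0.5, 1), ("B", "T", 1.0, 0.5, 1)])
        paths = simple_paths_to_target(g, "A", "T")
        assert len(paths) == 1
        assert paths[0].nodes == ("A", "B", "T")
        assert paths[0].total_delay == pytest.approx(2.0)
        assert paths[0].total_log_p == pytest.approx(2 * np.log(0.5))

    def test_cyclic_toy_matches_dfs_oracle(self):
        g = toy_graph([
            ("A", "B", 1.0, 0.5, 1), ("B", "C", 1.0, 0.5, 1),
            ("C", "A", 1.0, 0.5, 1), ("B", "T", 1.0, 0.5, 1),
            ("C", "T", 1.0, 0.5, -1), ("A", "T", 1.0, 0.5, 1),
        ])
        got = {p.nodes for p in simple_paths_to_target(g, "A", "T")}
        assert got == set(dfs_simple_paths(g, "A", "T"))

    def test_source_equal_target_yields_no_paths(self):
        g = toy_graph([("T", "B", 1.0, 0.5, 1), ("B", "T", 1.0, 0.5, 1)])
        assert simple_paths_to_target(g, "T", "T") == []

    def test_missing_target_rejected(self):
        g = toy_graph([("A", "B", 1.0, 0.5, 1)])
        with pytest.raises(ValueError):
            simple_paths_to_target(g, "A", "T")

    def test_path_enumeration_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(3, 9))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for a, b in itertools.permutations(range(n), 2):
                if rng.random() < 0.35:
                    g.add_edge(a, b, delay=float(rng.uniform(0.2, 2)),
                               p=float(rng.uniform(0.05, 1.0)), sign=1)
            for a, b in g.edges:
                g.edges[a, b]["log_p"] = float(np.log(g.edges[a, b]["p"]))
            target = n - 1
            for source in range(n - 1):
                got = {p.nodes for p in
                       simple_paths_to_target(g, source, target)}
                assert got == set(dfs_simple_paths(g, source, target))

    def test_default_network_paths_include_synaptic_delays(
            self, default_network):
        g = build_population_graph(default_network)
        for p in simple_paths_to_target(g, "L5_PTN_AFF"):
            hops = len(p.nodes) - 1
            assert p.total_delay >= 0.2 * hops


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

class TestNodeMetrics:
    def test_single_edge_path_metrics_equal_edge_values(self):
        g = toy_graph([("A", "T", 1.2, 0.3, -1)])
        m = node_metrics(g, "A", "T")
        assert m["n_simple_paths"] == 1
        assert m["shortest_path_delay"] == pytest.approx(1.2)
        assert m["avg_path_delay"] == pytest.approx(1.2)
        assert m["shortest_path_probability"] == pytest.approx(0.3)
        assert m["functional_effect"] == -1.0
        assert m["weighted_functional_effect"] == pytest.approx(-1.0)

    def test_worked_weighted_average_example(self):
        # two paths, delays {1.2, 2.4} ms, log-p weights {-1, -2}:
        # weighted mean = (1.2 * -1 + 2.4 * -2) / (-3) = 2.0 ms
        g = toy_graph([
            ("A", "T", 1.2, float(np.exp(-1.0)), 1),
            ("A", "B", 0.4, 1.0, 1),
            ("B", "T", 2.0, float(np.exp(-2.0)), 1),
        ])
        m = node_metrics(g, "A", "T")
        assert m["weighted_avg_path_delay"] == pytest.approx(2.0)

    def test_centralities_match_brute_force_on_toys(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(3, 9))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for a, b in itertools.permutations(range(n), 2):
                if rng.random() < 0.4:
                    g.add_edge(a, b, delay=float(rng.uniform(0.2, 2)),
                               p=0.5, log_p=float(np.log(0.5)), sign=1)
            cent = centralities(g)
            close, harm, btw = brute_force_centralities(g)
            for v in g:
                assert cent.loc[v, "closeness"] == pytest.approx(close[v])
                assert cent.loc[v, "harmonic"] == pytest.approx(harm[v])
                assert cent.loc[v, "betweenness"] == pytest.approx(btw[v])

    def test_excitatory_graph_effects_flip_with_one_edge(self):
        edges = [
            ("A", "B", 1.0, 0.5, 1), ("B", "T", 1.0, 0.5, 1),
            ("A", "T", 1.0, 0.5, 1),
        ]
        g = toy_graph(edges)
        assert all(p.effect == 1
                   for p in simple_paths_to_target(g, "A", "T"))
        g.edges["B", "T"]["sign"] = -1
        flipped = {p.nodes: p.effect
                   for p in simple_paths_to_target(g, "A", "T")}
        assert flipped[("A", "B", "T")] == -1
        assert flipped[("A", "T")] == 1

    def test_metrics_invariant_under_relabeling(self):
        g = toy_graph([
            ("A", "B", 1.0, 0.5, 1), ("B", "T", 0.7, 0.4, -1),
            ("A", "T", 1.5, 0.9, 1),
        ])
        relabeled = nx.relabel_nodes(g, {"A": "X", "B": "Y"})
        a = node_metrics(g, "A", "T")
        b = node_metrics(relabeled, "X", "T")
        for k in a:
            assert a[k] == pytest.approx(b[k], nan_ok=True)

    def test_delay_weighted_distance_switch(self):
        g = toy_graph([("A", "B", 5.0, 0.5, 1), ("B", "T", 5.0, 0.5, 1),
                       ("A", "T", 30.0, 0.5, 1)])
        hops = centralities(g, "hops")
        delay = centralities(g, "delay")
        assert hops.loc["T", "harmonic"] == pytest.approx(1.0 + 1.0)
        # by delay, A -> B -> T (10 ms) beats the direct 30 ms edge
        assert delay.loc["T", "harmonic"] == pytest.approx(1 / 10 + 1 / 5)

    def test_metrics_table_covers_all_nodes(self, default_network):
        g = build_population_graph(default_network)
        table = metrics_table(g)
        assert len(table) == 12
        assert table.loc["L5_PTN_AFF", "n_simple_paths"] >= 1
        wfe = table["weighted_functional_effect"].dropna()
        assert ((wfe >= -1 - 1e-9) & (wfe <= 1 + 1e-9)).all()
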