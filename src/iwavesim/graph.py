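"""Population-level directed graph of the circuit and structural metrics.

The 12 nodes are the six cortical populations and their six afferent
groups.  Each edge carries the empirical pairwise connection probability of
the built network, the mean realized synaptic delay (which includes the
0.2 ms synaptic transmission delay), and a functional sign (+1 excitatory,
-1 inhibitory).  All structural metrics are referenced to the corticospinal
output population (L5 PTN) through exhaustive simple-path enumeration.

Weighted path statistics use the log connection probabilities as weights
exactly as printed (the weights are negative; averages normalize by the
weight sum), with an absolute-value-weight variant behind a flag.
Centralities can measure distance in hops (default) or in delay.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

TARGET = "L5_PTN"

METRIC_COLUMNS = (
    "convergence", "divergence", "n_simple_paths", "shortest_path_delay",
    "avg_path_delay", "weighted_avg_path_delay", "std_path_delay",
    "weighted_std_path_delay", "shortest_path_probability",
    "avg_log_probability", "std_log_probability", "functional_effect",
    "weighted_functional_effect", "closeness", "harmonic", "betweenness",
)


@dataclass(frozen=True)
class SimplePath:
    """One non-repeating directed path ending at the target population."""

    nodes: tuple
    total_delay: float       # ms, sum of edge delays (0.2 ms synaptic incl.)
    total_log_p: float       # sum of log connection probabilities
    effect: int              # product of edge signs

    @property
    def probability(self) -> float:
        return float(np.exp(self.total_log_p))


def build_population_graph(network) -> nx.DiGraph:
    """Collapse the synapse table to a 12-node directed weighted graph.

    Edge probability is the realized connection frequency between the two
    populations (autapses excluded from the denominator for recurrent
    edges); edge delay is the mean realized synaptic delay.  Receptor
    co-transmission (AMPA+NMDA or GABA_A+GABA_B) is already collapsed to
    one synapse row per connection, hence one edge per population pair.
    """
    pops = network.neurons["population"]
    sizes = pops.value_counts().to_dict()
    for p, n in sizes.items():
        if n == 0:
            raise ValueError(f"population {p} has no members")
    pop_of = dict(zip(network.neurons["id"], pops))
    syn = network.synapses
    g = nx.DiGraph()
    g.add_nodes_from(sizes)
    pre_pop = syn["pre"].map(pop_of)
    post_pop = syn["post"].map(pop_of)
    grouped = syn.groupby([pre_pop, post_pop], observed=True)
    for (a, b), sub in grouped:
        n_possible = sizes[a] * sizes[b] - (sizes[a] if a == b else 0)
        p = len(sub) / n_possible
        g.add_edge(a, b,
                   p=p,
                   log_p=float(np.log(p)),
                   delay=float(sub["delay_ms"].mean()),
                   sign=int(sub["sign"].iloc[0]))
    return g


def simple_paths_to_target(graph: nx.DiGraph, source,
                           target=TARGET) -> list[SimplePath]:
    """All simple paths from ``source`` to the target population.

    For ``source == target`` the zero-length path is excluded and any walk
    that leaves and returns repeats the node, so the result is empty.
    """
    if target not in graph:
        raise ValueError(f"target {target} not in graph")
    if source not in graph:
        raise ValueError(f"source {source} not in graph")
    if source == target:
        return []
    out = []
    for nodes in nx.all_simple_paths(graph, source, target):
        delay = 0.0
        logp = 0.0
        effect = 1
        for a, b in itertools.pairwise(nodes):
            e = graph.edges[a, b]
            if e["p"] <= 0:
                raise ValueError(f"non-positive probability on {a}->{b}")
            delay += e["delay"]
            logp += e["log_p"]
            effect *= e["sign"]
        out.append(SimplePath(tuple(nodes), delay, logp, effect))
    return out


# ---------------------------------------------------------------------------
# Centralities (explicit formulas; distance in hops or delay)
# ---------------------------------------------------------------------------

def _edge_weight(distance: str):
    if distance == "hops":
        return None
    if distance == "delay":
        return "delay"
    raise ValueError(f"unknown distance '{distance}'")


def centralities(graph: nx.DiGraph, distance: str = "hops") -> pd.DataFrame:
    """Closeness, harmonic and betweenness centrality for every node.

    Closeness of v is (N - 1) / sum of d(u, v) over the nodes that reach v
    (0 if none); harmonic sums 1/d(u, v) over reachable u (unreachable
    nodes contribute 0); betweenness is the raw sum over ordered pairs
    (s, t) of the fraction of shortest s->t paths passing through v.
    """
    weight = _edge_weight(distance)
    nodes = list(graph.nodes)
    N = len(nodes)
    dist = dict(nx.all_pairs_dijkstra_path_length(graph, weight=weight)) \
        if weight else dict(nx.all_pairs_shortest_path_length(graph))
    close = {}
    harm = {}
    for v in nodes:
        incoming = [dist[u][v] for u in nodes
                    if u != v and v in dist.get(u, {})]
        close[v] = (N - 1) / sum(incoming) \
            if incoming and sum(incoming) > 0 else 0.0
        harm[v] = sum(1.0 / d for d in incoming if d > 0)
    btw = nx.betweenness_centrality(graph, normalized=False, weight=weight)
    return pd.DataFrame({
        "closeness": close, "harmonic": harm, "betweenness": btw,
    }).loc[nodes]


# ---------------------------------------------------------------------------
# Per-node metric set
# ---------------------------------------------------------------------------

def _weighted_mean_std(values, weights, absolute: bool = False):
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if absolute:
        w = np.abs(w)
    total = w.sum()
    if total == 0:
        return np.nan, np.nan
    mean = float((v * w).sum() / total)
    var = float((w * (v - mean) ** 2).sum() / total)
    # with as-printed negative weights the "variance" can come out negative;
    # report the signed-magnitude root so the convention stays invertible
    std = float(np.sign(var) * np.sqrt(abs(var)))
    return mean, std


def node_metrics(graph: nx.DiGraph, source, target=TARGET,
                 distance: str = "hops",
                 absolute_weights: bool = False) -> dict:
    """The full structural metric set of one node, referenced to the target.

    Path-dependent entries are NaN when no simple path exists.  Weighted
    statistics use the per-path total log probability as weights, as
    printed (set ``absolute_weights`` for the magnitude variant).
    """
    paths = simple_paths_to_target(graph, source, target)
    cent = centralities(graph, distance).loc[source]
    out = {
        "convergence": graph.in_degree(source),
        "divergence": graph.out_degree(source),
        "n_simple_paths": len(paths),
        "closeness": float(cent["closeness"]),
        "harmonic": float(cent["harmonic"]),
        "betweenness": float(cent["betweenness"]),
    }
    if not paths:
        for k in ("shortest_path_delay", "avg_path_delay",
                  "weighted_avg_path_delay", "std_path_delay",
                  "weighted_std_path_delay", "shortest_path_probability",
                  "avg_log_probability", "std_log_probability",
                  "functional_effect", "weighted_functional_effect"):
            out[k] = np.nan
        return out
    delays = np.array([p.total_delay for p in paths])
    logps = np.array([p.total_log_p for p in paths])
    effects = np.array([p.effect for p in paths], dtype=float)
    shortest = int(np.argmin(delays))
    wmean_d, wstd_d = _weighted_mean_std(delays, logps, absolute_weights)
    wmean_e, _ = _weighted_mean_std(effects, logps, absolute_weights)
    out.update({
        "shortest_path_delay": float(delays[shortest]),
        "avg_path_delay": float(delays.mean()),
        "weighted_avg_path_delay": wmean_d,
        "std_path_delay": float(delays.std()),
        "weighted_std_path_delay": wstd_d,
        "shortest_path_probability": paths[shortest].probability,
        "avg_log_probability": float(logps.mean()),
        "std_log_probability": float(logps.std()),
        "functional_effect": float(effects.mean()),
        "weighted_functional_effect": wmean_e,
    })
    return out


def metrics_table(graph: nx.DiGraph, target=TARGET,
                  distance: str = "hops") -> pd.DataFrame:
    """Node-by-metric table for every node in the graph."""
    rows = {
        v: node_metrics(graph, v, target, distance)
        for v in graph.nodes
    }
    return pd.DataFrame(rows).T[list(METRIC_COLUMNS)]
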