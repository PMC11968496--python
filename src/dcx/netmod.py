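"""Dense-module detection on the differential co-expression graph.

Implements a seed-and-grow molecular-complex detector in the MCODE family:

1. *Vertex weighting*: each vertex is weighted by k * density of the highest
   k-core of its closed neighborhood.
2. *Complex prediction*: starting from the highest-weighted unused vertex, the
   complex is the connected component (around the seed) of vertices whose
   weight is at least ``seed_weight * (1 - node_score_cutoff)``.
3. *Post-processing*: the complex is reduced to its k-core (k=2 by default,
   the "haircut") and split at cut edges — a reported module must be
   2-edge-connected, so a single bridge never fuses two dense modules.

Clusters are scored by ``density * n_nodes`` where density is the simple-graph
density 2E / (V (V - 1)).  Reported clusters are vertex-disjoint and sorted by
descending score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParameterError, ValidationError

__all__ = [
    "GeneCluster",
    "network_density",
    "cluster_score",
    "mcode_cluster",
    "select_significant",
    "graph_from_edges",
]


@dataclass(frozen=True)
class GeneCluster:
    member_nodes: frozenset
    n_nodes: int
    n_edges: int
    density: float
    mcode_score: float

    def __post_init__(self) -> None:
        if self.n_nodes >= 2:
            expected = network_density(self.n_nodes, self.n_edges)
            if abs(expected - self.density) > 1e-9:
                raise ValidationError("density inconsistent with node/edge counts")
            if abs(self.density * self.n_nodes - self.mcode_score) > 1e-9:
                raise ValidationError("score inconsistent with density * n_nodes")


def network_density(n_nodes: int, n_edges: int) -> float:
    """Simple-graph density 2E / (V (V - 1))."""
    if n_nodes < 2:
        raise ParameterError(f"density needs >= 2 nodes, got {n_nodes}")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValidationError(f"{n_edges} edges impossible for a simple graph on {n_nodes} nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def cluster_score(cluster: GeneCluster) -> float:
    """Module score: density * node count."""
    if cluster.n_nodes < 2:
        raise ParameterError("singleton cluster has no score")
    return cluster.density * cluster.n_nodes


def _cluster_from_nodes(graph: nx.Graph, nodes) -> GeneCluster:
    sub = graph.subgraph(nodes)
    n, e = sub.number_of_nodes(), sub.number_of_edges()
    d = network_density(n, e)
    return GeneCluster(frozenset(nodes), n, e, d, d * n)


def _vertex_weights(graph: nx.Graph) -> dict:
    """Bader–Hogue weighting: highest-k-core number x that core's density."""
    weights = {}
    for v in graph.nodes:
        hood = graph.subgraph([v, *graph.neighbors(v)])
        if hood.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_numbers = nx.core_number(hood)
        k = max(core_numbers.values())
        core = hood.subgraph([u for u, c in core_numbers.items() if c >= k])
        weights[v] = k * network_density(core.number_of_nodes(), core.number_of_edges())
    return weights


def mcode_cluster(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    degree_cutoff: int = 2,
    k_core: int = 2,
    haircut: bool = True,
) -> list[GeneCluster]:
    """Detect dense, vertex-disjoint modules; empty graph yields an empty list."""
    if not 0 <= node_score_cutoff < 1:
        raise ParameterError("node_score_cutoff must be in [0, 1)")
    if degree_cutoff < 0 or k_core < 1:
        raise ParameterError("invalid degree_cutoff / k_core")
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0:
        return []

    weights = _vertex_weights(g)
    unused = set(g.nodes)
    # deterministic seed order: weight desc, degree desc, then label
    seeds = sorted(g.nodes, key=lambda v: (-weights[v], -g.degree(v), str(v)))
    clusters: list[GeneCluster] = []
    for seed in seeds:
        if seed not in unused or g.degree(seed) < degree_cutoff:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        eligible = {v for v in unused if weights[v] >= threshold}
        eligible.add(seed)
        sub = g.subgraph(eligible)
        component = nx.node_connected_component(sub, seed)
        complex_sub = g.subgraph(component)
        if haircut:
            complex_sub = nx.k_core(complex_sub, k_core)
        elif nx.k_core(complex_sub, k_core).number_of_nodes() == 0:
            complex_sub = g.subgraph([])
        unused -= set(component)
        if complex_sub.number_of_nodes() == 0:
            continue
        # require 2-edge-connected modules: split at cut edges
        pruned = nx.Graph(complex_sub)
        pruned.remove_edges_from(list(nx.bridges(pruned)))
        for part in nx.connected_components(pruned):
            if len(part) >= k_core + 1:
                clusters.append(_cluster_from_nodes(g, part))
    clusters.sort(key=lambda c: (-c.mcode_score, -c.n_nodes, sorted(map(str, c.member_nodes))))
    return clusters


def select_significant(
    clusters: list[GeneCluster], min_score: float = 10.0, max_keep: int = 1
) -> list[GeneCluster]:
    """Keep clusters scoring >= min_score, top max_keep by score.

    Ties broken by more nodes, then lexicographically smallest member.
    """
    kept = [c for c in clusters if c.mcode_score >= min_score]
    kept.sort(key=lambda c: (-c.mcode_score, -c.n_nodes, sorted(map(str, c.member_nodes))))
    return kept[:max_keep]


def graph_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Build the differential co-expression graph from an edge table."""
    g = nx.Graph()
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        if a != b:
            g.add_edge(a, b)
    return g


def clusters_to_json(clusters: list[GeneCluster], path: str | Path) -> None:
    import json

    payload = [
        {
            "members": sorted(map(str, c.member_nodes)),
            "n_nodes": c.n_nodes,
            "n_edges": c.n_edges,
            "density": c.density,
            "mcode_score": c.mcode_score,
        }
        for c in clusters
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
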