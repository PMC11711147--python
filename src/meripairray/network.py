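"""PPI network filtering and MCODE molecular-complex detection.

MCODE weights every vertex by the density of the highest k-core of its
closed neighbourhood (weight = k_max * density of that core), then grows
complexes from the highest-weighted unused seed, admitting neighbours whose
weight is at least ``seed_weight * (1 - vwp)``.  A haircut pass removes
singly-connected members (clusters of two nodes are exempt, so a lone edge
survives as a minimal complex).  Clusters are disjoint and ranked by

    score = density * n = 2E / (n - 1),

the statistic Cytoscape's MCODE plugin reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .exceptions import ValidationError


def build_graph(edges: pd.DataFrame, score_cutoff: float = 0.4) -> nx.Graph:
    """Filtered, deduplicated, undirected PPI graph.

    Self-loops are dropped; duplicate A-B edges keep the maximum score;
    only edges with combined_score strictly greater than the cutoff are
    retained, so isolated nodes never enter the graph.
    """
    g = nx.Graph()
    for a, b, s in edges[["node_a", "node_b", "combined_score"]].itertuples(
        index=False
    ):
        if a == b:
            continue
        s = float(s)
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], s)
        else:
            g.add_edge(a, b, combined_score=s)
    drop = [
        (a, b) for a, b, d in g.edges(data=True) if d["combined_score"] <= score_cutoff
    ]
    g.remove_edges_from(drop)
    g.remove_nodes_from([v for v in g if g.degree(v) == 0])
    return g


def mcode_vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    """MCODE vertex weighting.

    weight(v) = k_max * density(highest k-core of G[N[v] ∪ {v}]), where
    k_max is the largest k with a non-empty k-core.  Vertices with degree
    below ``degree_cutoff`` are not scored (weight 0).
    """
    weights = {}
    for v in graph:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = list(graph[v]) + [v]
        sub = graph.subgraph(closed)
        core_num = nx.core_number(sub)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_num.items() if c >= k_max]
        core = sub.subgraph(core_nodes)
        weights[v] = float(k_max) * nx.density(core)
    return weights


@dataclass(frozen=True)
class MCODECluster:
    """A detected complex: members, internal edges and MCODE score."""

    seed: str
    members: tuple  # sorted node ids
    edge_count: int

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def density(self) -> float:
        return 2.0 * self.edge_count / (self.n * (self.n - 1))

    @property
    def score(self) -> float:
        return cluster_score(self.n, self.edge_count)


def _haircut(graph: nx.Graph, members: set) -> set:
    """Iteratively strip members connected to the rest of the cluster by a
    single edge; a two-node cluster is left intact."""
    members = set(members)
    while len(members) > 2:
        sub = graph.subgraph(members)
        drop = {v for v in members if sub.degree(v) < 2}
        if not drop:
            break
        members -= drop
    return members


def mcode_find_clusters(
    graph: nx.Graph,
    weights: dict | None = None,
    vwp: float = 0.2,
    haircut: bool = True,
    degree_cutoff: int = 2,
) -> list:
    """Seeded greedy complex prediction (disjoint clusters, ranked by score).

    Seeds are visited in decreasing weight order (ties by node id); a
    breadth-first expansion admits unvisited neighbours with weight >=
    seed_weight * (1 - vwp).  Nodes touched by an expansion are never reused,
    matching MCODE's single-membership behaviour.  Clusters that end up with
    fewer than two members are discarded.
    """
    if not 0 <= vwp < 1:
        raise ValidationError("vwp must lie in [0, 1)")
    if weights is None:
        weights = mcode_vertex_weights(graph, degree_cutoff)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited = set()
    clusters = []
    for seed in order:
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            u = frontier.pop(0)
            for nb in sorted(graph[u], key=str):
                if nb not in visited and weights[nb] >= threshold:
                    visited.add(nb)
                    members.add(nb)
                    frontier.append(nb)
        if haircut:
            members = _haircut(graph, members)
        if len(members) < 2:
            continue
        edge_count = graph.subgraph(members).number_of_edges()
        clusters.append(
            MCODECluster(
                seed=seed,
                members=tuple(sorted(members, key=str)),
                edge_count=edge_count,
            )
        )
    clusters.sort(key=lambda c: (-c.score, -c.n, str(c.seed)))
    return clusters


def cluster_score(n: int, edge_count: int) -> float:
    """MCODE cluster score 2E/(n-1) (= density * n)."""
    if n < 2:
        raise ValidationError("a cluster needs at least 2 nodes")
    if not 0 <= edge_count <= n * (n - 1) // 2:
        raise ValidationError("edge count outside [0, n(n-1)/2]")
    return 2.0 * edge_count / (n - 1)


def clusters_to_frame(clusters) -> pd.DataFrame:
    """Tabular export of ranked clusters."""
    rows = [
        (
            rank,
            c.seed,
            c.n,
            c.edge_count,
            c.density,
            c.score,
            ",".join(map(str, c.members)),
        )
        for rank, c in enumerate(clusters, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=["rank", "seed", "n", "edge_count", "density", "score", "members"],
    )
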