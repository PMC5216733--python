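"""Node topology indices for undirected simple graphs.

The seven per-node indices reported for correlation networks: degree, degree
centrality, betweenness, closeness, clustering coefficient, radiality and
average shortest path length (ASPL).  Correlation networks of small matched
cohorts are typically fragmented into small clusters, so every path-based
metric is computed within the node's connected component and normalized by
the component order n_c (the Cytoscape NetworkAnalyzer convention); global
normalization would zero out small-cluster structure.  Degree centrality
alone is normalized by the full graph order n (degree / (n - 1)).

Conventions:

* betweenness: Brandes accumulation, scaled by 2 / ((n_c - 1)(n_c - 2));
  0 when n_c < 3;
* closeness: (n_c - 1) / sum of distances to the component; 0 for a
  singleton (flagged);
* ASPL: mean distance to the rest of the component; 0 for a singleton;
* radiality: (D_c + 1 - ASPL) / D_c with D_c the component diameter; 1 by
  convention for singleton and two-node components (flagged when the
  formula's D_c >= 1 guard did not apply);
* clustering coefficient: 2 e_N / (k (k - 1)) with e_N edges among the k
  neighbors; 0 when k < 2.

Graphs are unweighted and undirected: correlation magnitude is an edge
attribute upstream, never a path weight.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import pandas as pd

TOPOLOGY_COLUMNS = ["degree", "degree_centrality", "betweenness", "closeness",
                    "clustering_coeff", "radiality", "aspl"]


@dataclass
class Graph:
    """Undirected simple graph: adjacency sets, no self-loops, no parallels."""

    adjacency: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "Graph":
        g = cls()
        for node in nodes:
            g.add_node(node)
        for a, b in edges:
            g.add_edge(a, b)
        return g

    def add_node(self, node) -> None:
        self.adjacency.setdefault(node, set())

    def add_edge(self, a, b) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        self.add_node(a)
        self.add_node(b)
        self.adjacency[a].add(b)
        self.adjacency[b].add(a)

    @property
    def nodes(self) -> list:
        return list(self.adjacency)

    @property
    def n_nodes(self) -> int:
        return len(self.adjacency)

    def degree(self, node) -> int:
        return len(self.adjacency[node])

    def edges(self) -> list[tuple]:
        return sorted({tuple(sorted((a, b))) for a, nbrs in self.adjacency.items()
                       for b in nbrs})

    def components(self) -> list[list]:
        seen: set = set()
        comps = []
        for start in self.adjacency:
            if start in seen:
                continue
            comp, queue = [], deque([start])
            seen.add(start)
            while queue:
                v = queue.popleft()
                comp.append(v)
                for w in self.adjacency[v]:
                    if w not in seen:
                        seen.add(w)
                        queue.append(w)
            comps.append(comp)
        return comps


@dataclass
class NodeTopology:
    degree: int
    degree_centrality: float
    betweenness: float
    closeness: float
    clustering_coeff: float
    radiality: float
    aspl: float
    component_order: int
    degenerate_component: bool  # singleton / two-node conventions applied


def shortest_paths(graph: Graph, source) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts sigma(s, t) from one source."""
    if source not in graph.adjacency:
        raise KeyError(f"source {source!r} not in graph")
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in graph.adjacency[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = sigma[v]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _brandes_raw(graph: Graph) -> dict:
    """Unnormalized betweenness (each unordered pair counted twice)."""
    bet = {v: 0.0 for v in graph.adjacency}
    for s in graph.adjacency:
        stack: list = []
        pred: dict = {v: [] for v in graph.adjacency}
        dist = {s: 0}
        sigma = {v: 0 for v in graph.adjacency}
        sigma[s] = 1
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in graph.adjacency[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist.get(w) == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in graph.adjacency}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bet[w] += delta[w]
    return bet


def node_metrics(graph: Graph) -> dict:
    """All seven indices for every node; raises on an empty graph."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    n = graph.n_nodes
    raw_bet = _brandes_raw(graph)
    out: dict = {}
    for comp in graph.components():
        nc = len(comp)
        comp_set = set(comp)
        dists = {v: shortest_paths(graph, v)[0] for v in comp}
        diameter = max((d for row in dists.values() for d in row.values()), default=0)
        for v in comp:
            k = graph.degree(v)
            dsum = sum(dists[v].values())
            aspl = dsum / (nc - 1) if nc > 1 else 0.0
            closeness = (nc - 1) / dsum if dsum > 0 else 0.0
            if nc >= 3:
                betweenness = raw_bet[v] / ((nc - 1) * (nc - 2))  # raw counts pairs twice
            else:
                betweenness = 0.0
            if k >= 2:
                nbrs = graph.adjacency[v]
                e_n = sum(1 for a in nbrs for b in graph.adjacency[a] if b in nbrs) // 2
                clustering = 2.0 * e_n / (k * (k - 1))
            else:
                clustering = 0.0
            degenerate = nc <= 2
            radiality = (diameter + 1.0 - aspl) / diameter if diameter >= 1 else 1.0
            out[v] = NodeTopology(
                degree=k,
                degree_centrality=k / (n - 1) if n > 1 else 0.0,
                betweenness=betweenness,
                closeness=closeness,
                clustering_coeff=clustering,
                radiality=radiality,
                aspl=aspl,
                component_order=nc,
                degenerate_component=degenerate,
            )
    return out


def topology_frame(metrics: dict) -> pd.DataFrame:
    """Tabular view of node_metrics output, sorted by node."""
    rows = {node: [getattr(m, c) for c in TOPOLOGY_COLUMNS] +
            [m.component_order, m.degenerate_component]
            for node, m in metrics.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=TOPOLOGY_COLUMNS + ["component_order",
                                                               "degenerate_component"])
    frame.index.name = "node"
    return frame.sort_index()


def network_topology(net) -> pd.DataFrame:
    """Topology table for a CorrelationNetwork (isolated nodes included)."""
    g = Graph.from_edges(net.edges, nodes=net.nodes)
    return topology_frame(node_metrics(g))
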