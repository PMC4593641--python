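"""Gene interaction networks: edge filtering, query subnetworks, random walk.

The composite functional-association network (GeneMANIA-style weighted
edge list) is first thinned to its strongest interactions (top 5% by
default).  For each query gene a small subnetwork is cut out: edge
weights ``w`` become distances ``d = max_w / w`` (heavier = closer) and
Dijkstra's algorithm selects the closest ``k`` neighbors (30 by
default).  Connections severed by the cut are replaced by a *sink*
node: each boundary gene is linked to the sink with the summed weight of
its removed edges, so that mass lost to the rest of the network is
modelled rather than ignored.  A random walk with restart at the query
then ranks the members; rank and Dijkstra distance feed the downstream
feature weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SINK",
    "WeightedGeneNetwork",
    "QuerySubnetwork",
    "filter_top_edges",
    "edge_distance",
    "build_subnetwork",
    "random_walk_ranks",
    "neighbor_weight",
    "read_edge_list",
]

#: Identifier of the synthetic sink node added to query subnetworks.
SINK = "__sink__"


class WeightedGeneNetwork:
    """Undirected gene-gene network with positive edge weights."""

    def __init__(self, edges: list[tuple[str, str, float]] | None = None):
        self._g = nx.Graph()
        for a, b, w in edges or []:
            self.add_edge(a, b, w)

    def add_edge(self, a: str, b: str, w: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        if w <= 0:
            raise ValueError(f"edge weight must be positive, got {w}")
        if self._g.has_edge(a, b):  # duplicate pairs are summed
            self._g[a][b]["weight"] += w
        else:
            self._g.add_edge(a, b, weight=w)

    def add_node(self, n: str) -> None:
        self._g.add_node(n)

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self._g.edges(data=True)]

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return self._g[a][b]["weight"]

    def neighbors(self, n: str) -> set[str]:
        return set(self._g.neighbors(n)) if n in self._g else set()

    def __contains__(self, n: str) -> bool:
        return n in self._g

    @property
    def max_weight(self) -> float:
        """Maximum edge weight in the network (cached by networkx attrs)."""
        if self._g.number_of_edges() == 0:
            raise ValueError("network has no edges")
        return max(d["weight"] for _, _, d in self._g.edges(data=True))

    def graph(self) -> nx.Graph:
        return self._g


@dataclass
class QuerySubnetwork:
    """Dijkstra neighborhood of one query gene, with sink and walk ranks.

    ``distances`` are Dijkstra distances over ``d = max_w / w`` edge
    lengths (0 for the query itself, >= 1 for every neighbor);
    ``ranks`` maps each non-query, non-sink member to its random-walk
    rank 1..k (query rank is 0 by convention); ``walk_probabilities``
    is the stationary distribution of the restart walk over all nodes
    including the sink.
    """

    query: str
    members: list[str]                      # query first, then neighbors
    graph: nx.Graph                         # members (+ sink if present)
    distances: dict[str, float]
    max_w: float                            # full filtered network's max weight
    ranks: dict[str, int] = field(default_factory=dict)
    walk_probabilities: dict[str, float] = field(default_factory=dict)

    @property
    def neighbors(self) -> list[str]:
        return self.members[1:]

    @property
    def has_sink(self) -> bool:
        return SINK in self.graph

    def top_neighbors(self, k: int) -> list[str]:
        """The k best-ranked neighbors (all, if fewer)."""
        if not self.ranks and self.neighbors:
            raise ValueError("ranks not computed; call random_walk_ranks first")
        ordered = sorted(self.ranks, key=self.ranks.__getitem__)
        return ordered[:k]


def filter_top_edges(net: WeightedGeneNetwork, fraction: float) -> WeightedGeneNetwork:
    """Keep the ceil(fraction * |E|) heaviest edges.

    Edges tied with the cutoff weight are all kept, so the result can
    slightly exceed the nominal count.  Nodes stripped of every edge
    remain as isolates.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    out = WeightedGeneNetwork()
    for n in net.nodes:
        out.add_node(n)
    edges = net.edges()
    if not edges:
        return out
    n_keep = math.ceil(fraction * len(edges))
    weights = sorted((w for _, _, w in edges), reverse=True)
    cutoff = weights[n_keep - 1]
    for a, b, w in edges:
        if w >= cutoff:
            out.add_edge(a, b, w)
    return out


def edge_distance(w: float, max_w: float) -> float:
    """Distance of an edge of weight ``w``: ``max_w / w`` (>= 1)."""
    if w <= 0:
        raise ValueError(f"edge weight must be positive, got {w}")
    if w > max_w:
        raise ValueError(f"edge weight {w} exceeds network maximum {max_w}")
    return max_w / w


def build_subnetwork(
    net: WeightedGeneNetwork, query: str, k_sub: int = 30
) -> QuerySubnetwork:
    """Cut the ``k_sub`` Dijkstra-closest neighbors of ``query`` out of
    ``net`` and attach the sink node for severed connections.

    Distance ties at the boundary are broken by gene identifier, keeping
    exactly ``k_sub`` neighbors (fewer when the connected component is
    smaller).  Each member that lost at least one edge in the cut gains
    a sink edge whose weight is the sum of its removed edge weights.
    An isolated query yields a singleton subnetwork with no sink.
    """
    if query not in net:
        raise KeyError(f"query gene {query!r} not in network")
    max_w = net.max_weight if net.n_edges() else 0.0
    if not net.neighbors(query):
        g = nx.Graph()
        g.add_node(query)
        return QuerySubnetwork(query, [query], g, {query: 0.0}, max_w=max_w)
    lengths = nx.single_source_dijkstra_path_length(
        net.graph(), query, weight=lambda a, b, d: max_w / d["weight"]
    )
    reachable = sorted(
        ((d, n) for n, d in lengths.items() if n != query), key=lambda t: t
    )
    chosen = [n for _, n in reachable[:k_sub]]
    members = [query] + chosen
    member_set = set(members)

    sub = nx.Graph()
    sub.add_nodes_from(members)
    sink_weight: dict[str, float] = {}
    for m in members:
        for nb in net.neighbors(m):
            w = net.weight(m, nb)
            if nb in member_set:
                if not sub.has_edge(m, nb):
                    sub.add_edge(m, nb, weight=w)
            else:
                sink_weight[m] = sink_weight.get(m, 0.0) + w
    for m, w in sink_weight.items():
        sub.add_edge(m, SINK, weight=w)

    distances = {m: (0.0 if m == query else lengths[m]) for m in members}
    return QuerySubnetwork(query, members, sub, distances, max_w=max_w)


def random_walk_ranks(
    sub: QuerySubnetwork,
    alpha: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> dict[str, int]:
    """Rank subnetwork members by a random walk with restart at the query.

    The walker follows edges with probability proportional to weight and
    teleports back to the query with probability ``alpha`` at each step.
    Power iteration runs until the L1 change drops below ``tol``.
    Neighbors are ranked 1, 2, ... by descending stationary probability;
    ties break by ascending Dijkstra distance, then gene identifier.
    The query's own rank is 0 by convention; the sink is never ranked.

    Fills ``sub.ranks`` and ``sub.walk_probabilities`` and returns the
    rank map.
    """
    if not sub.neighbors:
        raise ValueError("subnetwork has no non-query member to rank")
    nodes = list(sub.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    W = np.zeros((n, n))
    for a, b, d in sub.graph.edges(data=True):
        W[idx[a], idx[b]] = d["weight"]
        W[idx[b], idx[a]] = d["weight"]
    row_sums = W.sum(axis=1)
    # isolated nodes (none in practice) would self-teleport via restart
    P = np.divide(W, row_sums[:, None], out=np.zeros_like(W), where=row_sums[:, None] > 0)

    restart = np.zeros(n)
    restart[idx[sub.query]] = 1.0
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        p_next = alpha * restart + (1 - alpha) * (P.T @ p)
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    else:
        raise RuntimeError(
            f"random walk did not converge within {max_iter} iterations "
            f"(L1 residual {np.abs(p_next - p).sum():.3e})"
        )

    sub.walk_probabilities = {nodes[i]: float(p[i]) for i in range(n)}
    candidates = [m for m in sub.members if m != sub.query]
    ordered = sorted(
        candidates,
        key=lambda m: (-sub.walk_probabilities[m], sub.distances[m], m),
    )
    sub.ranks = {m: r for r, m in enumerate(ordered, start=1)}
    return sub.ranks


def neighbor_weight(sub: QuerySubnetwork, neighbor: str) -> float:
    """Weight of a neighbor: ``max_w / d`` over its Dijkstra distance."""
    if neighbor not in sub.distances or neighbor == sub.query:
        raise KeyError(f"{neighbor!r} is not a neighbor in this subnetwork")
    return sub.max_w / sub.distances[neighbor]


def read_edge_list(path: str) -> WeightedGeneNetwork:
    """Read a 3-column tab-separated edge list (gene_a, gene_b, weight).

    Duplicate pairs are summed; lines starting with ``#`` are comments.
    """
    net = WeightedGeneNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            net.add_edge(fields[0], fields[1], float(fields[2]))
    return net
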