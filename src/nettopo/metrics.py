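"""First-principles topological metrics for undirected simple networks.

Every quantity here is computed directly from its definition — neighbour-pair
triangle counting for clustering, breadth-first search from every node for
the shortest-path statistics — rather than delegated to a graph library's
summary routines, so each definition is explicit and independently testable.

Conventions
-----------
* Shortest-path accounting is over ORDERED pairs (n, m), n != m, so a
  connected network of N nodes has N*(N-1) finite pairs.  This convention is
  the one used by common network-analysis GUIs and makes the finite-pair
  percentage denominator N*(N-1).
* The clustering coefficient of a node I with k_I >= 2 neighbours is
  C_I = 2*n_I / (k_I*(k_I - 1)) where n_I counts edges among the neighbours;
  for k_I < 2 the coefficient is undefined (returned as None).  The network
  mean averages over defined nodes only by default; ``count_low_degree_as_zero``
  switches to the convention that treats k < 2 nodes as contributing 0.
* The characteristic path length is the mean distance over finite ordered
  pairs only ("between two connected nodes").
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "DistanceSummary",
    "TopologyReport",
    "DegreeDistribution",
    "node_degree",
    "node_clustering",
    "mean_clustering",
    "all_pairs_distances",
    "diameter",
    "avg_neighbors",
    "degree_distribution",
    "count_components",
    "topology_report",
]


@dataclass(frozen=True)
class DistanceSummary:
    """Shortest-path statistics over ordered node pairs.

    ``distance_histogram`` maps each finite distance k to the number of
    ordered pairs (n, m) with L(n, m) = k; symmetric paths are counted in
    both directions, so every histogram value is even.
    """

    finite_ordered_pair_count: int
    percent_of_all_pairs: float
    characteristic_path_length: float
    diameter: int | None
    distance_histogram: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class DegreeDistribution:
    """Node counts per degree class (degree >= 1); zero-degree nodes tallied apart.

    Degree-0 nodes cannot enter a log-log fit (log 0 undefined) so they are
    excluded from ``points`` but reported in ``n_zero_degree``.
    """

    points: tuple[tuple[int, int], ...]
    n_zero_degree: int


@dataclass(frozen=True)
class TopologyReport:
    """One row of the per-network topology table."""

    network_name: str
    n_components: int
    n_nodes: int
    n_edges: int
    mean_clustering_coefficient: float
    diameter: int | None
    shortest_paths: DistanceSummary
    characteristic_path_length: float
    avg_neighbors: float

    def to_row(self) -> dict[str, object]:
        """Serialize with 3-decimal rounding, matching tabular report style."""
        sp = self.shortest_paths
        return {
            "Network": self.network_name,
            "Connected components": self.n_components,
            "Number of nodes": self.n_nodes,
            "Number of edges": self.n_edges,
            "Clustering coefficient": round(self.mean_clustering_coefficient, 3),
            "Network diameter": self.diameter,
            "Shortest paths": sp.finite_ordered_pair_count,
            "Shortest paths (%)": round(100.0 * sp.percent_of_all_pairs, 0),
            "Characteristic path length": round(self.characteristic_path_length, 3),
            "Avg. number of neighbors": round(self.avg_neighbors, 3),
        }


def node_degree(net: nx.Graph, node: str) -> int:
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    return len(net.adj[node])


def node_clustering(net: nx.Graph, node: str) -> float | None:
    """C_I = 2*n_I/(k_I*(k_I-1)); None when k_I < 2 (undefined)."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    neighbors = [n for n in net.adj[node] if n != node]
    k = len(neighbors)
    if k < 2:
        return None
    links = 0
    neighbor_set = set(neighbors)
    for i, u in enumerate(neighbors):
        # count each neighbour pair once
        links += sum(1 for v in neighbors[i + 1:] if v in net.adj[u] and v in neighbor_set)
    return 2.0 * links / (k * (k - 1))


def mean_clustering(net: nx.Graph, count_low_degree_as_zero: bool = False) -> float:
    """Arithmetic mean of node clustering coefficients.

    By default only nodes with degree >= 2 (where the coefficient is defined)
    enter the mean; 0.0 is returned when no such node exists.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("mean_clustering of an empty network is undefined")
    values = []
    for node in net.nodes:
        c = node_clustering(net, node)
        if c is not None:
            values.append(c)
        elif count_low_degree_as_zero:
            values.append(0.0)
    if not values:
        return 0.0
    return sum(values) / len(values)


def _bfs_distances(net: nx.Graph, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in net.adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def all_pairs_distances(net: nx.Graph) -> DistanceSummary:
    """BFS from every node; ordered-pair histogram, CPL, diameter, coverage."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("all_pairs_distances requires at least 2 nodes")
    histogram: Counter[int] = Counter()
    total = 0
    count = 0
    for source in net.nodes:
        for target, d in _bfs_distances(net, source).items():
            if target == source:
                continue
            histogram[d] += 1
            total += d
            count += 1
    return DistanceSummary(
        finite_ordered_pair_count=count,
        percent_of_all_pairs=count / (n * (n - 1)),
        characteristic_path_length=total / count if count else float("nan"),
        diameter=max(histogram) if histogram else None,
        distance_histogram=dict(sorted(histogram.items())),
    )


def diameter(net: nx.Graph) -> int | None:
    """Longest finite shortest path; None when no two nodes are connected."""
    return all_pairs_distances(net).diameter


def avg_neighbors(net: nx.Graph) -> float:
    """Mean degree, 2E/N."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("avg_neighbors of an empty network is undefined")
    return 2.0 * net.number_of_edges() / n


def degree_distribution(net: nx.Graph) -> DegreeDistribution:
    counts: Counter[int] = Counter(len(net.adj[node]) for node in net.nodes)
    n_zero = counts.pop(0, 0)
    return DegreeDistribution(
        points=tuple(sorted(counts.items())),
        n_zero_degree=n_zero,
    )


def count_components(net: nx.Graph) -> int:
    """Number of connected components, by repeated BFS over unvisited nodes."""
    seen: set[str] = set()
    n_components = 0
    for node in net.nodes:
        if node not in seen:
            n_components += 1
            seen.update(_bfs_distances(net, node))
    return n_components


def topology_report(net: nx.Graph) -> TopologyReport:
    """Assemble the full per-network topology row."""
    sp = all_pairs_distances(net)
    return TopologyReport(
        network_name=net.graph.get("name", ""),
        n_components=count_components(net),
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        mean_clustering_coefficient=mean_clustering(net),
        diameter=sp.diameter,
        shortest_paths=sp,
        characteristic_path_length=sp.characteristic_path_length,
        avg_neighbors=avg_neighbors(net),
    )
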