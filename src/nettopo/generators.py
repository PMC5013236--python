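"""Seeded synthetic-network generators spanning the study's structural regimes.

The comparative analysis needs reference networks from three regimes:

* **BA scale-free** — growth with preferential attachment (Barabási–Albert).
  Convention: the seed graph is the complete graph on m+1 nodes, and each
  new node attaches to m DISTINCT existing nodes drawn preferentially by
  degree without replacement.  This yields a connected graph with
  C(m+1, 2) + (N - m - 1) * m edges (253 at N=128, m=2), minimum degree m,
  and a heavy-tailed degree distribution.
* **Hierarchical** — a deterministic Ravasz-style construction (a 5-clique
  module replicated recursively, peripheral nodes wired to the root hub),
  optionally perturbed by a small seeded edge rewiring.  Mean clustering
  stays above 0.5 and per-degree clustering C(k) falls with k.
* **Random controls** — Erdős–Rényi G(N, p), plus deterministic fixtures
  (star, ring, complete, a two-component graph).

All stochastic models draw from a single explicitly seeded
``numpy.random.Generator``; identical config means byte-identical
serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .netio import network

__all__ = [
    "GeneratorConfig",
    "generate",
    "generate_barabasi_albert",
    "generate_erdos_renyi",
    "generate_hierarchical",
    "generate_two_component",
    "fixture_suite",
]

_STOCHASTIC_MODELS = {"barabasi_albert", "erdos_renyi", "two_component"}
_MODELS = _STOCHASTIC_MODELS | {"hierarchical", "star", "ring", "complete"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Model name plus the parameters it needs.

    ``n_nodes`` is the total node count for most models; for ``hierarchical``
    the size is 5**levels and n_nodes is ignored.  ``seed`` is mandatory for
    stochastic models.
    """

    model: str
    n_nodes: int = 0
    m: int = 2
    p: float = 0.0
    levels: int = 3
    seed: int | None = None
    name: str | None = None

    def validate(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(_MODELS)}")
        if self.model in _STOCHASTIC_MODELS and self.seed is None:
            raise ValueError(f"model {self.model!r} is stochastic: field 'seed' is required")
        if self.model == "barabasi_albert":
            if self.m < 1:
                raise ValueError("field 'm' must be >= 1")
            if self.n_nodes <= self.m:
                raise ValueError("field 'n_nodes' must exceed 'm' for barabasi_albert")
        elif self.model == "erdos_renyi":
            if self.n_nodes < 1:
                raise ValueError("field 'n_nodes' must be >= 1")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError("field 'p' must lie in [0, 1]")
        elif self.model == "hierarchical":
            if not 1 <= self.levels <= 4:
                raise ValueError("field 'levels' must lie in 1..4 (5**levels nodes)")
        elif self.model in {"star", "ring", "complete"}:
            minimum = {"star": 2, "ring": 3, "complete": 1}[self.model]
            if self.n_nodes < minimum:
                raise ValueError(f"field 'n_nodes' must be >= {minimum} for {self.model}")
        elif self.model == "two_component":
            if self.n_nodes < 6:
                raise ValueError("field 'n_nodes' must be >= 6 for two_component")


def _labels(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate(config: GeneratorConfig) -> nx.Graph:
    """Build the network a config describes (clean, deterministic per seed)."""
    config.validate()
    model = config.model
    if model == "barabasi_albert":
        net = generate_barabasi_albert(config.n_nodes, config.m, config.seed)
    elif model == "erdos_renyi":
        net = generate_erdos_renyi(config.n_nodes, config.p, config.seed)
    elif model == "hierarchical":
        net = generate_hierarchical(config.levels, seed=config.seed)
    elif model == "two_component":
        net = generate_two_component(config.n_nodes, config.m, config.seed)
    elif model == "star":
        labels = _labels("s", config.n_nodes)
        net = network("star", edges=[(labels[0], leaf) for leaf in labels[1:]])
    elif model == "ring":
        labels = _labels("r", config.n_nodes)
        net = network(
            "ring", edges=[(labels[i], labels[(i + 1) % len(labels)]) for i in range(len(labels))]
        )
    else:  # complete
        labels = _labels("k", config.n_nodes)
        net = network("complete", edges=list(combinations(labels, 2)), nodes=labels)
    if config.name:
        net.graph["name"] = config.name
    return net


def generate_barabasi_albert(n: int, m: int, seed: int) -> nx.Graph:
    """Growth + preferential attachment; seed graph K_{m+1}, m distinct targets."""
    if n <= m:
        raise ValueError("barabasi_albert requires n > m")
    rng = np.random.default_rng(seed)
    labels = _labels("v", n)
    net = network(f"BA_N{n}_m{m}_s{seed}", edges=list(combinations(labels[: m + 1], 2)))
    # attachment pool: every node appears once per unit of degree
    pool: list[str] = [lab for lab in labels[: m + 1] for _ in range(m)]
    for new in labels[m + 1:]:
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(pool[int(rng.integers(len(pool)))])
        for t in sorted(targets):
            net.add_edge(new, t)
            pool.append(t)
        pool.extend([new] * m)
    return net


def generate_erdos_renyi(n: int, p: float, seed: int) -> nx.Graph:
    """G(n, p): each of the C(n,2) pairs is an edge independently with probability p."""
    rng = np.random.default_rng(seed)
    labels = _labels("e", n)
    net = network(f"ER_N{n}_p{p}_s{seed}", nodes=labels)
    for u, v in combinations(labels, 2):
        if rng.random() < p:
            net.add_edge(u, v)
    return net


def generate_hierarchical(
    levels: int, seed: int | None = None, rewire_rate: float = 0.02
) -> nx.Graph:
    """Ravasz-style hierarchical module network with 5**levels nodes.

    Level 1 is a 5-clique with a designated root.  Each further level makes
    four peripheral copies of the previous level alongside the central one
    and wires every peripheral node of the copies to the root, producing a
    hub hierarchy whose per-degree clustering decreases with degree.  When a
    seed is given, ``rewire_rate`` * E randomly chosen edges are rewired to
    random non-edges, adding mild disorder without destroying the regime.
    """
    if not 1 <= levels <= 4:
        raise ValueError("levels must lie in 1..4 (5**levels nodes; >4 exceeds 3000 nodes)")
    n_total = 5 ** levels
    labels = _labels("h", n_total)
    edges: set[tuple[int, int]] = set(combinations(range(5), 2))
    root = 0
    peripheral = [1, 2, 3, 4]
    size = 5
    for _ in range(2, levels + 1):
        new_edges = set(edges)
        new_peripheral: list[int] = []
        for copy in range(1, 5):
            offset = copy * size
            new_edges.update((u + offset, v + offset) for u, v in edges)
            new_peripheral.extend(p + offset for p in peripheral)
        for p in new_peripheral:
            new_edges.add((root, p))
        edges = new_edges
        peripheral = new_peripheral
        size *= 5
    net = network(
        f"HIER_L{levels}" + (f"_s{seed}" if seed is not None else ""),
        edges=[(labels[u], labels[v]) for u, v in sorted(edges)],
        nodes=labels,
    )
    if seed is not None and rewire_rate > 0:
        _rewire(net, np.random.default_rng(seed), rewire_rate)
    return net


def _rewire(net: nx.Graph, rng: np.random.Generator, rate: float) -> None:
    """Replace ~rate*E random edges with random non-edges, in place."""
    n_moves = int(round(rate * net.number_of_edges()))
    nodes = sorted(net.nodes)
    for _ in range(n_moves):
        edges = sorted(map(tuple, map(sorted, net.edges)))
        u, v = edges[int(rng.integers(len(edges)))]
        for _attempt in range(100):
            a, b = (nodes[int(rng.integers(len(nodes)))] for _ in range(2))
            if a != b and not net.has_edge(a, b):
                net.remove_edge(u, v)
                net.add_edge(a, b)
                break


def generate_two_component(n: int, m: int, seed: int) -> nx.Graph:
    """A BA-like main component of n-3 nodes plus a disjoint triangle.

    Mirrors the shape of a randomizer run that yields two components, the
    smaller being a 3-node one.
    """
    main = generate_barabasi_albert(n - 3, m, seed)
    tri = _labels("t", 3)
    net = network(f"TWO_COMP_N{n}_s{seed}", nodes=tri)
    net.add_edges_from(main.edges)
    net.add_nodes_from(main.nodes)
    net.add_edges_from([(tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])])
    return net


def fixture_suite() -> dict[str, nx.Graph]:
    """Deterministic named fixtures used across examples and tests."""
    triangle = network("triangle", edges=[("A", "B"), ("B", "C"), ("A", "C")])
    path_labels = _labels("p", 11)
    path_11 = network("path_11", edges=list(zip(path_labels, path_labels[1:])))
    star_11 = generate(GeneratorConfig(model="star", n_nodes=11, name="star_11"))
    ring_10 = generate(GeneratorConfig(model="ring", n_nodes=10, name="ring_10"))
    complete_5 = generate(GeneratorConfig(model="complete", n_nodes=5, name="complete_5"))
    two_triangles = network(
        "two_triangles",
        edges=[("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")],
    )
    two_component = generate(
        GeneratorConfig(model="two_component", n_nodes=128, m=2, seed=20160824,
                        name="two_component_125_3")
    )
    suite = [triangle, path_11, star_11, ring_10, complete_5, two_triangles, two_component]
    return {net.graph["name"]: net for net in suite}
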