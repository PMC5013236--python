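"""Hub identification and topology classification.

Hubs are the nodes whose degree is at least one standard deviation above the
network mean — the conventional operational definition of a high-control
node in signalling-network studies.  The standard deviation is the
population (divide-by-N) one by default, since the node set is the whole
population, not a sample.

Classification separates two regimes observed in curated vs text-mined
signalling networks:

* ``scale_free_BA`` — a Barabási–Albert-like network: power-law degree
  distribution with negative exponent, low mean clustering, clustering
  uncorrelated with degree.
* ``hierarchical`` — scale-free but highly clustered, with per-degree mean
  clustering C(k) that falls with degree (clustering correlated with
  degree).

The mean clustering coefficient is the unambiguous separator between the two
regimes in practice (curated/KEGG/BA-model networks sit below ~0.1,
text-mined ones above ~0.5), so the rule is conjunctive: high clustering
AND degree-correlated clustering mean hierarchical; a good negative-exponent
degree fit AND low clustering mean BA-like.  The numeric cut-offs are one
defensible reading and are exposed in :class:`ClassifierConfig` rather than
hard-coded.

A small-world annotation is attached as a heuristic (short characteristic
path length relative to ln N / ln <k>, with near-full reachability); it is
an interpretation of the usual qualitative claim, not a canonical formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import fits, metrics

logger = logging.getLogger(__name__)

__all__ = [
    "HubSet",
    "ClassifierConfig",
    "Evidence",
    "TopologyClass",
    "identify_hubs",
    "classify_evidence",
    "classify_topology",
]


@dataclass(frozen=True)
class HubSet:
    """Degree threshold (mean + 1 SD) and the nodes meeting it."""

    network_name: str
    mean_degree: float
    degree_sd: float
    threshold: float
    hubs: tuple[tuple[str, int], ...]
    degenerate: bool = False  # all degrees equal (SD = 0): every node qualifies

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.hubs)


@dataclass(frozen=True)
class ClassifierConfig:
    """Cut-offs for the scale-free vs hierarchical decision rule."""

    hierarchical_min_clustering: float = 0.3
    hierarchical_min_abs_r: float = 0.5
    scale_free_min_r_squared: float = 0.5
    scale_free_max_clustering: float = 0.3
    small_world_cpl_factor: float = 1.5
    small_world_min_reachability: float = 0.9


@dataclass(frozen=True)
class Evidence:
    """The measurements the classification rule is a pure function of."""

    gamma: float | None
    r_squared: float | None
    mean_clustering: float
    degree_cc_r: float | None
    cpl: float
    avg_neighbors: float
    n_nodes: int
    reachability: float
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class TopologyClass:
    label: str  # scale_free_BA | hierarchical | indeterminate
    small_world: bool
    evidence: Evidence


def identify_hubs(net: nx.Graph, sample_sd: bool = False) -> HubSet:
    """Nodes with degree >= mean + 1 standard deviation.

    ``sample_sd=True`` uses the N-1 (sample) standard deviation instead of
    the population one.  When every node has the same degree the SD is 0 and
    all nodes meet the threshold; the result is flagged ``degenerate`` since
    "hub" is then uninformative.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("identify_hubs requires at least 2 nodes")
    degrees = {node: len(net.adj[node]) for node in net.nodes}
    values = np.array(list(degrees.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1 if sample_sd else 0))
    threshold = mean + sd
    hubs = sorted(
        ((node, k) for node, k in degrees.items() if k >= threshold),
        key=lambda item: (-item[1], item[0]),
    )
    degenerate = sd == 0.0
    if degenerate:
        logger.warning(
            "identify_hubs(%s): all degrees equal (SD=0); every node meets the "
            "threshold and the hub set is uninformative",
            net.graph.get("name", "?"),
        )
    return HubSet(
        network_name=net.graph.get("name", ""),
        mean_degree=mean,
        degree_sd=sd,
        threshold=threshold,
        hubs=tuple(hubs),
        degenerate=degenerate,
    )


def classify_evidence(evidence: Evidence, config: ClassifierConfig | None = None) -> TopologyClass:
    """Apply the decision rule to an evidence tuple (pure function)."""
    cfg = config or ClassifierConfig()
    label = "indeterminate"
    if (
        evidence.mean_clustering >= cfg.hierarchical_min_clustering
        and evidence.degree_cc_r is not None
        and abs(evidence.degree_cc_r) >= cfg.hierarchical_min_abs_r
    ):
        label = "hierarchical"
    elif (
        evidence.gamma is not None
        and evidence.gamma < 0
        and evidence.r_squared is not None
        and evidence.r_squared >= cfg.scale_free_min_r_squared
        and evidence.mean_clustering < cfg.scale_free_max_clustering
    ):
        label = "scale_free_BA"
    small_world = False
    if evidence.avg_neighbors > 1 and evidence.n_nodes > 1 and math.isfinite(evidence.cpl):
        bound = cfg.small_world_cpl_factor * math.log(evidence.n_nodes) / math.log(
            evidence.avg_neighbors
        )
        small_world = (
            evidence.cpl <= bound
            and evidence.reachability >= cfg.small_world_min_reachability
        )
    return TopologyClass(label=label, small_world=small_world, evidence=evidence)


def classify_topology(net: nx.Graph, config: ClassifierConfig | None = None) -> TopologyClass:
    """Measure a network and classify it as BA-like scale-free or hierarchical.

    Individual fit failures (too few degree classes, no clustered nodes) are
    recorded in the evidence notes and lead to ``indeterminate`` rather than
    an exception.
    """
    notes: list[str] = []
    gamma = r_squared = None
    try:
        degree_fit = fits.fit_degree_distribution(net)
        gamma, r_squared = degree_fit.gamma, degree_fit.r_squared
    except fits.FitError as exc:
        notes.append(f"degree fit failed: {exc}")
    degree_cc_r = None
    try:
        cc_fit = fits.fit_degree_vs_clustering(net)
        degree_cc_r = cc_fit.r
    except fits.FitError as exc:
        notes.append(f"degree-clustering fit failed: {exc}")
    if net.number_of_nodes() >= 2:
        sp = metrics.all_pairs_distances(net)
        cpl, reach = sp.characteristic_path_length, sp.percent_of_all_pairs
    else:
        cpl, reach = float("nan"), 0.0
        notes.append("too few nodes for path statistics")
    evidence = Evidence(
        gamma=gamma,
        r_squared=r_squared,
        mean_clustering=metrics.mean_clustering(net) if net.number_of_nodes() else 0.0,
        degree_cc_r=degree_cc_r,
        cpl=cpl,
        avg_neighbors=metrics.avg_neighbors(net) if net.number_of_nodes() else 0.0,
        n_nodes=net.number_of_nodes(),
        reachability=reach,
        notes=tuple(notes),
    )
    return classify_evidence(evidence, config)
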