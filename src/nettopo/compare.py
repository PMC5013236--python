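"""Multi-network comparison: topology tables, fits, hubs, class, Venn overlaps.

``run_comparison`` produces, for each input network, the full per-network
result bundle (topology row, degree fit, degree–clustering fit, hub set,
topology class) plus node- and hub-overlap partitions across networks.

Overlap partitions are exact Venn regions: each label is assigned to exactly
one region, keyed by the subset of network names containing it, so region
counts sum to the size of the union and satisfy inclusion–exclusion.  Label
comparison is case-insensitive by default (curated tables mix "ACTIN",
"Actin" and "actin" for the same molecule) with the first-seen casing
preserved in the output; exact matching is available via flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from . import analysis, fits, metrics, netio

logger = logging.getLogger(__name__)

__all__ = ["NetworkResult", "ComparisonReport", "venn_regions", "run_comparison"]

MAX_VENN_SETS = 5


@dataclass(frozen=True)
class NetworkResult:
    """Everything computed for one network."""

    topology: metrics.TopologyReport
    degree_fit: fits.PowerLawFit | None
    degree_cc_fit: fits.PowerLawFit | None
    hubs: analysis.HubSet | None
    topo_class: analysis.TopologyClass
    fit_errors: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComparisonReport:
    per_network: dict[str, NetworkResult]
    node_overlap: dict[tuple[str, ...], tuple[str, ...]] | None
    hub_overlap: dict[tuple[str, ...], tuple[str, ...]] | None

    def to_dict(self) -> dict:
        def fit_row(f: fits.PowerLawFit | None) -> dict | None:
            return f.to_row() if f is not None else None

        def overlap_obj(overlap) -> dict | None:
            if overlap is None:
                return None
            return {" & ".join(region): sorted(members) for region, members in overlap.items()}

        return {
            "networks": {
                name: {
                    "topology": res.topology.to_row(),
                    "degree_fit": fit_row(res.degree_fit),
                    "degree_vs_clustering_fit": fit_row(res.degree_cc_fit),
                    "hubs": [list(h) for h in res.hubs.hubs] if res.hubs else None,
                    "hub_threshold": round(res.hubs.threshold, 3) if res.hubs else None,
                    "class": res.topo_class.label,
                    "small_world": res.topo_class.small_world,
                    "fit_errors": list(res.fit_errors),
                }
                for name, res in self.per_network.items()
            },
            "node_overlap": overlap_obj(self.node_overlap),
            "hub_overlap": overlap_obj(self.hub_overlap),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def venn_regions(
    sets: Mapping[str, Iterable[str]], case_insensitive: bool = True
) -> dict[tuple[str, ...], tuple[str, ...]]:
    """Partition the union of 1–5 named label sets into exact Venn regions.

    Returns a map from region (sorted tuple of the set names containing the
    label) to the sorted labels in that region.  Empty regions are omitted.
    Five sets is the practical ceiling for a readable Venn layout.
    """
    names = list(sets)
    if not 1 <= len(names) <= MAX_VENN_SETS:
        raise ValueError(f"venn_regions supports 1..{MAX_VENN_SETS} sets, got {len(names)}")

    def norm(label: str) -> str:
        label = label.strip()
        return label.lower() if case_insensitive else label

    canonical: dict[str, str] = {}  # normalized -> first-seen casing
    membership: dict[str, set[str]] = {}
    for name in names:
        for label in sets[name]:
            key = norm(label)
            canonical.setdefault(key, label.strip())
            membership.setdefault(key, set()).add(name)
    regions: dict[tuple[str, ...], list[str]] = {}
    for key, owners in membership.items():
        region = tuple(sorted(owners))
        regions.setdefault(region, []).append(canonical[key])
    return {region: tuple(sorted(members)) for region, members in sorted(regions.items())}


def run_comparison(
    nets: list[nx.Graph],
    config: analysis.ClassifierConfig | None = None,
    main_components: bool = False,
    case_insensitive_overlap: bool = True,
) -> ComparisonReport:
    """Analyse each network and cross-compare node and hub sets.

    ``main_components=True`` adds an ``MC_<name>`` variant of every
    disconnected network, as is customary before path-based statistics.
    Individual fit failures are recorded per network, never fatal.  Overlap
    partitions are computed when 2–5 networks are present; otherwise they
    are omitted (logged).
    """
    names = [net.graph.get("name", "") for net in nets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate network names in comparison: {names}")
    expanded = list(nets)
    if main_components:
        for net in nets:
            if not nx.is_connected(net) and net.number_of_nodes() > 0:
                expanded.append(netio.main_component(net))

    per_network: dict[str, NetworkResult] = {}
    for net in expanded:
        name = net.graph.get("name", "")
        errors: list[str] = []
        degree_fit = degree_cc_fit = None
        try:
            degree_fit = fits.fit_degree_distribution(net)
        except fits.FitError as exc:
            errors.append(str(exc))
        try:
            degree_cc_fit = fits.fit_degree_vs_clustering(net)
        except fits.FitError as exc:
            errors.append(str(exc))
        hubs = analysis.identify_hubs(net) if net.number_of_nodes() >= 2 else None
        per_network[name] = NetworkResult(
            topology=metrics.topology_report(net),
            degree_fit=degree_fit,
            degree_cc_fit=degree_cc_fit,
            hubs=hubs,
            topo_class=analysis.classify_topology(net, config),
            fit_errors=tuple(errors),
        )

    node_overlap = hub_overlap = None
    if 1 <= len(per_network) <= MAX_VENN_SETS:
        node_overlap = venn_regions(
            {name: list(net.nodes) for name, net in zip(per_network, expanded)},
            case_insensitive=case_insensitive_overlap,
        )
        hub_sets = {
            name: list(res.hubs.labels)
            for name, res in per_network.items()
            if res.hubs is not None
        }
        if hub_sets:
            hub_overlap = venn_regions(hub_sets, case_insensitive=case_insensitive_overlap)
    else:
        logger.info(
            "run_comparison: %d networks exceed the %d-set Venn limit; overlap maps omitted",
            len(per_network), MAX_VENN_SETS,
        )
    return ComparisonReport(
        per_network=per_network, node_overlap=node_overlap, hub_overlap=hub_overlap
    )
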