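"""Reading, writing, cleaning, merging and decomposing interaction networks.

Networks are undirected graphs over string node labels, carried as
:class:`networkx.Graph` instances (clean networks) or
:class:`networkx.MultiGraph` instances (raw, as-read networks that may still
contain self-loops and duplicate edges).  The network name is stored in
``G.graph["name"]``.

Node identity is the exact label after stripping leading/trailing whitespace;
no case folding is performed, since distinct molecules are routinely
distinguished only by case or punctuation ("F-actin" vs "actin", "[Ca2+]i").

Cleaning (self-loop and duplicate removal) is always an explicit step:
readers preserve the raw edge multiset so that curation artefacts remain
auditable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "Stoplist",
    "ParseError",
    "SchemaError",
    "network",
    "read_edge_list",
    "read_sif",
    "read_interaction_table",
    "read_stoplist",
    "clean_network",
    "merge_networks",
    "remove_nodes",
    "connected_components",
    "main_component",
    "write_edge_list",
    "write_sif",
    "networks_equal",
]


class ParseError(ValueError):
    """A malformed line or row in a network file."""


class SchemaError(ValueError):
    """An interaction table missing a mandatory column."""


@dataclass(frozen=True)
class InteractionRecord:
    """One row of a curated interaction table.

    The table schema mirrors manually curated signalling databases: a source
    molecule, a free-text interaction label, a target molecule, and optional
    curation metadata (alias, physiological role, literature reference,
    notes).  Only source and target are topologically meaningful; the rest is
    carried as annotation.
    """

    source_molecule: str
    interaction: str
    target_molecule: str
    alias: str = ""
    role: str = ""
    reference: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.source_molecule.strip():
            raise ValueError("source_molecule must be non-empty")
        if not self.target_molecule.strip():
            raise ValueError("target_molecule must be non-empty")


@dataclass(frozen=True)
class Stoplist:
    """Node labels to remove from a network (nonspecific terms).

    Matching is exact-label after whitespace trimming, never substring:
    filtering "membrane" must not remove "membrane receptor".
    """

    terms: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_iterable(cls, terms: Iterable[str]) -> "Stoplist":
        cleaned = frozenset(t.strip() for t in terms if t.strip())
        return cls(terms=cleaned)


def network(name: str, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()) -> nx.Graph:
    """Build a clean named network from explicit edges and isolated nodes."""
    g = nx.Graph(name=name)
    g.add_nodes_from(n.strip() for n in nodes)
    for u, v in edges:
        u, v = u.strip(), v.strip()
        if u != v:
            g.add_edge(u, v)
        else:
            g.add_node(u)
    return g


def _name_from_path(path: str | Path) -> str:
    return Path(path).stem


def read_edge_list(path: str | Path, delimiter: str = "\t") -> nx.MultiGraph:
    """Read a delimited edge list into a raw (multi)graph.

    Each non-comment line holds ``node_a<delim>node_b`` (extra fields are
    ignored); a single-field line declares an isolated node.  Duplicate lines
    and self-loops are preserved as read — call :func:`clean_network` to
    collapse them.
    """
    path = Path(path)
    g = nx.MultiGraph(name=_name_from_path(path))
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = [f.strip() for f in stripped.split(delimiter)]
            fields = [f for f in fields if f]
            if not fields:
                raise ParseError(f"{path}:{lineno}: line has no fields")
            if len(fields) == 1:
                g.add_node(fields[0])
            else:
                g.add_edge(fields[0], fields[1])
    return g


def read_sif(path: str | Path) -> nx.MultiGraph:
    """Read a Cytoscape SIF file (``node relation node [node ...]``).

    Relation labels are kept as edge annotation only; topology is undirected.
    A bare node line declares an isolated node; a two-token line (node plus
    relation, no target) is malformed.
    """
    path = Path(path)
    g = nx.MultiGraph(name=_name_from_path(path))
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) == 1:
                g.add_node(tokens[0])
            elif len(tokens) == 2:
                raise ParseError(
                    f"{path}:{lineno}: SIF line has a relation but no target node"
                )
            else:
                source, relation = tokens[0], tokens[1]
                for target in tokens[2:]:
                    g.add_edge(source, target, interaction=relation)
    return g


_MANDATORY_COLUMNS = ("source molecule", "interaction", "target molecule")
_OPTIONAL_COLUMNS = ("alias", "role", "reference", "notes")


def read_interaction_table(path: str | Path, delimiter: str | None = None) -> nx.MultiGraph:
    """Read a curated interaction table (TSV or CSV) into a raw graph.

    The header must name at least Source molecule, Interaction and Target
    molecule (case-insensitive).  Every row becomes one edge annotated with
    its :class:`InteractionRecord`; duplicate pairs survive until cleaning,
    at which point their records are pooled on the single surviving edge.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    g = nx.MultiGraph(name=_name_from_path(path))
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty table") from None
        lowered = [h.strip().lower() for h in header]
        col: dict[str, int] = {}
        for name in _MANDATORY_COLUMNS:
            if name not in lowered:
                raise SchemaError(f"{path}: missing mandatory column {name!r}")
            col[name] = lowered.index(name)
        for name in _OPTIONAL_COLUMNS:
            if name in lowered:
                col[name] = lowered.index(name)

        def cell(row: Sequence[str], name: str) -> str:
            idx = col.get(name)
            if idx is None or idx >= len(row):
                return ""
            return row[idx].strip()

        for rowno, row in enumerate(reader, start=2):
            if not any(f.strip() for f in row):
                continue
            source = cell(row, "source molecule")
            target = cell(row, "target molecule")
            if not source or not target:
                raise ParseError(f"{path}: row {rowno}: empty source or target molecule")
            record = InteractionRecord(
                source_molecule=source,
                interaction=cell(row, "interaction"),
                target_molecule=target,
                alias=cell(row, "alias"),
                role=cell(row, "role"),
                reference=cell(row, "reference"),
                notes=cell(row, "notes"),
            )
            g.add_edge(source, target, record=record)
    return g


def read_stoplist(path: str | Path) -> Stoplist:
    """Read a plain-text stoplist, one label per line, ``#`` comments."""
    terms = []
    with Path(path).open() as fh:
        for line in fh:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                terms.append(stripped)
    return Stoplist.from_iterable(terms)


def clean_network(net: nx.Graph | nx.MultiGraph, name: str | None = None) -> nx.Graph:
    """Collapse a raw graph to a simple undirected graph.

    Removes self-loops and duplicate edges; nodes isolated by loop removal
    are kept (they still count as molecules).  ``record`` annotations from
    parallel raw edges are pooled into a ``records`` list on the surviving
    edge.  Idempotent.
    """
    out = nx.Graph(name=name if name is not None else net.graph.get("name", ""))
    out.add_nodes_from(net.nodes)
    n_loops = 0
    for u, v, data in net.edges(data=True):
        if u == v:
            n_loops += 1
            continue
        if out.has_edge(u, v):
            edge = out[u][v]
        else:
            out.add_edge(u, v)
            edge = out[u][v]
            edge["records"] = []
            if "interaction" in data:
                edge["interaction"] = data["interaction"]
        if "record" in data:
            edge["records"].append(data["record"])
        elif "records" in data:
            edge["records"].extend(data["records"])
    n_dupes = net.number_of_edges() - n_loops - out.number_of_edges()
    if n_loops or n_dupes:
        logger.info(
            "clean_network(%s): removed %d self-loops, %d duplicate edges",
            out.graph.get("name", "?"), n_loops, n_dupes,
        )
    return out


def merge_networks(nets: Sequence[nx.Graph], name: str) -> nx.Graph:
    """Union of several networks: union of node sets and of cleaned edge sets."""
    if not nets:
        raise ValueError("merge_networks requires at least one network")
    out = nx.Graph(name=name)
    for net in nets:
        cleaned = clean_network(net)
        out.add_nodes_from(cleaned.nodes)
        out.add_edges_from(cleaned.edges)
    return out


def remove_nodes(net: nx.Graph, stoplist: Stoplist, drop_isolated: bool = False) -> nx.Graph:
    """Remove stoplist nodes (exact label match) and all incident edges.

    Stoplist terms absent from the network are ignored and logged.  Nodes
    left isolated by the removal are kept by default; ``drop_isolated=True``
    also drops them (both conventions for downstream node counts are
    defensible, so the choice is explicit).
    """
    present = stoplist.terms & set(net.nodes)
    missing = stoplist.terms - present
    if missing:
        logger.info(
            "remove_nodes(%s): %d stoplist terms not present: %s",
            net.graph.get("name", "?"), len(missing), sorted(missing),
        )
    out = net.copy()
    out.remove_nodes_from(present)
    if present:
        logger.info(
            "remove_nodes(%s): removed %d nonspecific nodes", net.graph.get("name", "?"), len(present)
        )
    if drop_isolated:
        isolated = [n for n in out.nodes if out.degree(n) == 0]
        out.remove_nodes_from(isolated)
        if isolated:
            logger.info(
                "remove_nodes(%s): dropped %d isolated nodes", net.graph.get("name", "?"), len(isolated)
            )
    return out


def _component_key(nodes: set[str]) -> tuple[int, str]:
    # sort by size descending, ties by lexicographically smallest member
    return (-len(nodes), min(nodes))


def connected_components(net: nx.Graph) -> list[nx.Graph]:
    """Maximal connected subgraphs, largest first (ties by smallest label)."""
    comps = sorted(nx.connected_components(net), key=_component_key)
    name = net.graph.get("name", "")
    out = []
    for i, nodes in enumerate(comps, start=1):
        sub = net.subgraph(nodes).copy()
        sub.graph["name"] = f"{name}_cc{i}"
        out.append(sub)
    return out


def main_component(net: nx.Graph) -> nx.Graph:
    """The component with the most nodes, renamed ``MC_<name>``."""
    if net.number_of_nodes() == 0:
        raise ValueError("main_component of an empty network is undefined")
    nodes = min(nx.connected_components(net), key=_component_key)
    sub = net.subgraph(nodes).copy()
    sub.graph["name"] = f"MC_{net.graph.get('name', '')}"
    return sub


def _sorted_edges(net: nx.Graph) -> list[tuple[str, str]]:
    return sorted(tuple(sorted(e)) for e in net.edges)


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a deterministic TSV edge list (sorted; isolated nodes as bare lines)."""
    path = Path(path)
    covered = {n for e in net.edges for n in e}
    with path.open("w") as fh:
        for u, v in _sorted_edges(net):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(set(net.nodes) - covered):
            fh.write(f"{n}\n")


def write_sif(net: nx.Graph, path: str | Path, default_relation: str = "pp") -> None:
    """Write a deterministic SIF file, one edge per line.

    Edge ``interaction`` annotation is used as the relation label when
    present; otherwise ``default_relation``.  Relation labels containing
    whitespace are collapsed to underscores (SIF is whitespace-delimited).
    """
    path = Path(path)
    covered = {n for e in net.edges for n in e}
    with path.open("w") as fh:
        for u, v in _sorted_edges(net):
            relation = net[u][v].get("interaction", default_relation) or default_relation
            relation = "_".join(str(relation).split())
            fh.write(f"{u} {relation} {v}\n")
        for n in sorted(set(net.nodes) - covered):
            fh.write(f"{n}\n")


def networks_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Topological equality: same node set and same unordered edge set."""
    return set(a.nodes) == set(b.nodes) and set(map(frozenset, a.edges)) == set(
        map(frozenset, b.edges)
    )
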