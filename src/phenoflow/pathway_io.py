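"""KGML pathway parsing and conversion to signed Boolean networks.

Curated signal-transduction maps (KGML, the KEGG Markup Language) are read
into :class:`PathwayGraph` objects, converted to Boolean sub-networks by a
fixed interaction-type mapping, merged on stable gene identifiers and split
into connected components.

Interaction-type mapping (gene regulation vs. complex formation):

=====================  =================
KGML relation subtype  Boolean operation
=====================  =================
activation             MAJ (+1 edge)
expression             MAJ (+1 edge)
inhibition             MAJ (-1 edge)
binding/association    AND (complex node)
complex                AND (complex node)
dissociation           AND (complex node)
missing interaction    skipped
remove                 skipped
=====================  =================

Any other subtype is preserved verbatim in the :class:`PathwayGraph` and
skipped (with a logged count) during Boolean conversion.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .network import AND, MAJ, BooleanNetwork, NetworkError, NodeSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "PathwayNode",
    "PathwayEdge",
    "KGMLParseError",
    "KGMLStructureError",
    "ACTIVATING_TYPES",
    "INHIBITING_TYPES",
    "COMPLEX_TYPES",
    "SKIPPED_TYPES",
    "KNOWN_TYPES",
    "parse_kgml",
    "pathway_to_boolean",
    "merge_networks",
    "connected_components",
    "largest_component",
    "filter_pathways",
]

ACTIVATING_TYPES = frozenset({"activation", "expression"})
INHIBITING_TYPES = frozenset({"inhibition"})
COMPLEX_TYPES = frozenset({"binding/association", "complex", "dissociation"})
SKIPPED_TYPES = frozenset({"missing interaction", "remove"})
KNOWN_TYPES = ACTIVATING_TYPES | INHIBITING_TYPES | COMPLEX_TYPES | SKIPPED_TYPES


class KGMLParseError(ValueError):
    """Malformed XML; the message names the offending line."""


class KGMLStructureError(ValueError):
    """Structurally invalid KGML (e.g. a relation names a missing entry)."""


@dataclass(frozen=True)
class PathwayNode:
    entry_id: str
    gene_ids: tuple[str, ...]
    node_class: str  # "gene" | "complex"
    label: str = ""


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    kegg_type: str


@dataclass
class PathwayGraph:
    """Entries and relations of one KGML pathway, before Boolean conversion."""

    pathway_id: str
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[PathwayEdge] = field(default_factory=list)

    def node_map(self) -> dict[str, PathwayNode]:
        return {n.entry_id: n for n in self.nodes}

    def unmapped_types(self) -> Counter:
        return Counter(e.kegg_type for e in self.edges if e.kegg_type not in KNOWN_TYPES)

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for n in self.nodes:
            out.update(n.gene_ids)
        return out


# ---------------------------------------------------------------------------
# KGML parsing
# ---------------------------------------------------------------------------

def parse_kgml(source: str | Path) -> PathwayGraph:
    """Parse a KGML document (path or XML text) into a :class:`PathwayGraph`.

    Gene entries become ``gene`` nodes carrying the (possibly multiple)
    stable gene identifiers listed in their ``name`` attribute; ``group``
    entries become ``complex`` nodes holding the union of their components'
    gene ids.  Every relation subtype is preserved verbatim; relations with
    no subtype fall back to the relation's ``type`` attribute.
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        text = source
    else:
        text = Path(source).read_text()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:  # position is (line, column)
        line, col = exc.position
        raise KGMLParseError(f"malformed KGML at line {line}, column {col}: {exc}") from exc

    pathway_id = root.get("name", root.get("title", "pathway"))
    nodes: list[PathwayNode] = []
    entry_genes: dict[str, tuple[str, ...]] = {}
    group_components: dict[str, list[str]] = {}
    seen_ids: set[str] = set()

    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is None:
            raise KGMLStructureError("entry without an id attribute")
        if eid in seen_ids:
            raise KGMLStructureError(f"duplicate entry id {eid!r}")
        seen_ids.add(eid)
        etype = entry.get("type", "")
        graphics = entry.find("graphics")
        label = ""
        if graphics is not None and graphics.get("name"):
            label = graphics.get("name", "").split(",")[0].strip()
        if etype == "group":
            group_components[eid] = [c.get("id", "") for c in entry.findall("component")]
            nodes.append(PathwayNode(eid, (), "complex", label))
        else:
            genes = tuple(entry.get("name", "").split())
            entry_genes[eid] = genes
            nodes.append(PathwayNode(eid, genes, etype or "gene", label))

    # resolve group components into member gene ids
    resolved: list[PathwayNode] = []
    for n in nodes:
        if n.node_class == "complex":
            members: list[str] = []
            for cid in group_components[n.entry_id]:
                if cid not in seen_ids:
                    raise KGMLStructureError(
                        f"group {n.entry_id!r} references missing entry {cid!r}"
                    )
                members.extend(entry_genes.get(cid, ()))
            resolved.append(PathwayNode(n.entry_id, tuple(members), "complex", n.label))
        else:
            resolved.append(n)
    nodes = resolved

    edges: list[PathwayEdge] = []
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in seen_ids or e2 not in seen_ids:
            raise KGMLStructureError(
                f"relation references missing entry ({e1!r} -> {e2!r})"
            )
        subtypes = [s.get("name", "") for s in rel.findall("subtype")]
        if not subtypes:
            subtypes = [rel.get("type", "unknown")]
        for st in subtypes:
            edges.append(PathwayEdge(e1, e2, st))

    return PathwayGraph(pathway_id, nodes, edges)


# ---------------------------------------------------------------------------
# Boolean conversion
# ---------------------------------------------------------------------------

def _complex_id(members: Sequence[str]) -> str:
    return "+".join(sorted(members))


def pathway_to_boolean(pathway: PathwayGraph) -> BooleanNetwork:
    """Convert one pathway to a Boolean sub-network.

    Gene regulation (activation/expression/inhibition) becomes a signed edge
    into a MAJ node; complex formation (binding/association, complex,
    dissociation) materializes an AND node identified by the sorted tuple of
    member gene ids, fed by +1 edges from each participant.  Regulation
    whose target is a complex is redistributed onto the complex members so
    AND nodes never receive inhibiting edges.  Unmapped subtypes are skipped
    and counted in ``net.meta["unmapped"]``.
    """
    net = BooleanNetwork()
    nmap = pathway.node_map()
    # booleans node ids backing each entry
    entry_nodes: dict[str, list[str]] = {}

    def ensure_gene(gid: str, label: str = "") -> None:
        if gid not in net.nodes:
            net.add_node(gid, MAJ, label or gid)

    def ensure_complex(members: Sequence[str], label: str = "") -> str:
        cid = _complex_id(members)
        if cid not in net.nodes:
            net.nodes[cid] = NodeSpec(AND, label or cid)
            for m in sorted(set(members)):
                ensure_gene(m)
                net.add_edge(m, cid, 1)
        return cid

    for n in pathway.nodes:
        if n.node_class == "complex":
            if n.gene_ids:
                entry_nodes[n.entry_id] = [ensure_complex(n.gene_ids, n.label)]
            else:
                entry_nodes[n.entry_id] = []
        elif n.node_class == "gene":
            for g in n.gene_ids:
                ensure_gene(g, n.label if len(n.gene_ids) == 1 else g)
            entry_nodes[n.entry_id] = list(n.gene_ids)
        else:  # compound/map/ortholog entries are not modeled
            entry_nodes[n.entry_id] = []

    unmapped: Counter = Counter()
    skipped = 0
    existing: set[tuple[str, str, int]] = {(e.src, e.dst, e.sign) for e in net.edges}

    def add_edge_once(src: str, dst: str, sign: int) -> None:
        key = (src, dst, sign)
        if key not in existing:
            existing.add(key)
            net.add_edge(src, dst, sign)

    def regulation_targets(entry_id: str) -> list[str]:
        """MAJ targets backing an entry; complexes devolve to their members."""
        out: list[str] = []
        for nid in entry_nodes.get(entry_id, []):
            if net.nodes[nid].rule == AND:
                out.extend(m for m in nid.split("+"))
            else:
                out.append(nid)
        return out

    for edge in pathway.edges:
        kt = edge.kegg_type
        if kt in SKIPPED_TYPES:
            skipped += 1
            continue
        if kt in ACTIVATING_TYPES or kt in INHIBITING_TYPES:
            sign = 1 if kt in ACTIVATING_TYPES else -1
            for s in entry_nodes.get(edge.source, []):
                for t in regulation_targets(edge.target):
                    add_edge_once(s, t, sign)
        elif kt in COMPLEX_TYPES:
            members: list[str] = []
            for eid in (edge.source, edge.target):
                pn = nmap.get(eid)
                if pn is not None:
                    members.extend(pn.gene_ids)
            if members:
                cid = _complex_id(members)
                if cid not in net.nodes:
                    net.nodes[cid] = NodeSpec(AND, cid)
                for p in entry_nodes.get(edge.source, []) + entry_nodes.get(edge.target, []):
                    if p != cid:
                        add_edge_once(p, cid, 1)
        else:
            unmapped[kt] += 1

    if unmapped:
        logger.info(
            "pathway %s: skipped %d edges with unmapped interaction types %s",
            pathway.pathway_id, sum(unmapped.values()), dict(unmapped),
        )
    net.meta["unmapped"] = dict(unmapped)
    net.meta["skipped"] = skipped
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Merging and components
# ---------------------------------------------------------------------------

def merge_networks(nets: Sequence[BooleanNetwork]) -> BooleanNetwork:
    """Union sub-networks on stable node identifiers.

    Nodes with the same id are unified; parallel edges with identical sign
    collapse.  When the same id carries MAJ in one pathway and AND in
    another, AND wins (the complex constraint — all parts present — is the
    stricter one); both edge sets are retained.
    """
    merged = BooleanNetwork()
    for net in nets:
        for nid, spec in net.nodes.items():
            if nid not in merged.nodes:
                merged.nodes[nid] = spec
            elif merged.nodes[nid].rule != spec.rule:
                label = merged.nodes[nid].label or spec.label
                merged.nodes[nid] = NodeSpec(AND, label)
    seen: set[tuple[str, str, int]] = set()
    for net in nets:
        for e in net.edges:
            key = (e.src, e.dst, e.sign)
            if key not in seen:
                seen.add(key)
                merged.add_edge(*key)
    return merged


def connected_components(net: BooleanNetwork) -> list[BooleanNetwork]:
    """Weakly connected components (direction ignored), largest first.

    Equal-size ties are ordered by the lexicographically smallest sorted
    node-id set, so the result is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((e.src, e.dst) for e in net.edges)
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), [str(x) for x in c]))
    return [net.subnetwork(c) for c in comps]


def largest_component(net: BooleanNetwork) -> BooleanNetwork:
    """The major connected component (first of :func:`connected_components`)."""
    if not net.nodes:
        raise NetworkError("cannot take the largest component of an empty network")
    return connected_components(net)[0]


def filter_pathways(
    pathways: Iterable[PathwayGraph],
    markers: Iterable[str],
    min_count: int = 6,
) -> list[PathwayGraph]:
    """Keep pathways containing at least ``min_count`` of the given markers.

    Mirrors the map-selection step in which only pathways carrying a minimum
    number of process-associated markers are retained.
    """
    marker_set = set(markers)
    return [p for p in pathways if len(p.gene_ids() & marker_set) >= min_count]
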