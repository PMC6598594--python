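"""Signed Boolean network container and its JSON dialect.

A :class:`BooleanNetwork` is a directed, signed graph of genes/complexes.
Each node carries an update rule:

* ``MAJ`` — majority: the node turns ON when its active activating inputs
  outnumber its active inhibiting inputs (ties hold the current value).
* ``AND`` — conjunction: the node (a molecular complex) is ON only when
  every input is ON.  AND nodes accept only activating (+1) inputs.

The on-disk format is a plain JSON dialect::

    {"nodes": [{"id": ..., "rule": "MAJ", "label": ...}],
     "edges": [{"src": ..., "dst": ..., "sign": 1}]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

MAJ = "MAJ"
AND = "AND"

__all__ = ["MAJ", "AND", "NodeSpec", "Edge", "BooleanNetwork", "NetworkError"]


class NetworkError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class NodeSpec:
    rule: str = MAJ
    label: str = ""

    def __post_init__(self) -> None:
        if self.rule not in (MAJ, AND):
            raise NetworkError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True, order=True)
class Edge:
    src: str
    dst: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkError(f"edge sign must be +1 or -1, got {self.sign!r}")


@dataclass
class BooleanNetwork:
    """Directed signed graph with per-node Boolean update rules.

    ``nodes`` maps node id -> :class:`NodeSpec` (insertion order is the
    canonical node order used for state vectors).  ``meta`` holds run
    bookkeeping (e.g. counts of unmapped interaction types) and is excluded
    from equality and serialization.
    """

    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    meta: dict = field(default_factory=dict, compare=False)

    # -- construction helpers -------------------------------------------------

    def add_node(self, node_id: str, rule: str = MAJ, label: str = "") -> None:
        if node_id in self.nodes:
            raise NetworkError(f"duplicate node id {node_id!r}")
        self.nodes[node_id] = NodeSpec(rule, label or str(node_id))

    def add_edge(self, src: str, dst: str, sign: int = 1) -> None:
        self.edges.append(Edge(src, dst, sign))

    # -- basic queries --------------------------------------------------------

    @property
    def node_order(self) -> list[str]:
        return list(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def in_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.dst == node_id]

    def out_degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if e.src == node_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges) == set(other.edges)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`NetworkError` on failure.

        Invariants: edge endpoints exist, AND nodes receive only +1 edges,
        no duplicated (src, dst, sign) triple.
        """
        seen: set[Edge] = set()
        for e in self.edges:
            if e.src not in self.nodes or e.dst not in self.nodes:
                raise NetworkError(f"edge {e} references a missing node")
            if e in seen:
                raise NetworkError(f"duplicate edge {e}")
            seen.add(e)
            if self.nodes[e.dst].rule == AND and e.sign != 1:
                raise NetworkError(
                    f"AND node {e.dst!r} has an inhibiting input from {e.src!r}"
                )

    # -- graph views ----------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid, spec in self.nodes.items():
            g.add_node(nid, rule=spec.rule, label=spec.label)
        for e in self.edges:
            g.add_edge(e.src, e.dst, sign=e.sign)
        return g

    def subnetwork(self, node_ids: Iterable[str]) -> "BooleanNetwork":
        keep = set(node_ids)
        nodes = {nid: spec for nid, spec in self.nodes.items() if nid in keep}
        edges = [e for e in self.edges if e.src in keep and e.dst in keep]
        return BooleanNetwork(nodes, edges)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": nid, "rule": spec.rule, "label": spec.label}
                for nid, spec in self.nodes.items()
            ],
            "edges": [
                {"src": e.src, "dst": e.dst, "sign": e.sign} for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "BooleanNetwork":
        net = cls()
        for n in data["nodes"]:
            net.add_node(n["id"], n.get("rule", MAJ), n.get("label", ""))
        for e in data["edges"]:
            net.add_edge(e["src"], e["dst"], int(e["sign"]))
        return net

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BooleanNetwork":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))
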