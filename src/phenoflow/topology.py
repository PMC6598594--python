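"""Topological node scoring and gene-signature extraction.

Each gene/complex node of the Boolean network is scored by combining two
centrality metrics:

* **out-degree** — the number of nodes it regulates directly;
* **eccentricity** ``E = 1 / max(minPathLen)`` — the inverse of the longest
  shortest directed distance from the node to any reachable node, a proxy
  for its direct *and* indirect downstream influence.  A node that reaches
  nothing (a sink) gets ``E = 0`` (the limit of 1/infinity).

Nodes are ranked on each metric (rank 1 = largest, ties share the mean of
the tied positions) and combined into

    S_G = -log(R_OD + R_E)

so higher scores mark nodes whose removal would disrupt the most paths.
The signature is the set of nodes with ``S_G`` at or above a threshold
(-2.5 in the reference analysis, natural log), optionally completed with a
clamped inducer node that is appended without being scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import BooleanNetwork, NetworkError

__all__ = ["Signature", "eccentricity", "score_nodes", "select_signature"]


@dataclass
class Signature:
    """Ordered marker list selected by score threshold."""

    genes: list[str]
    threshold: float
    includes_inducer: bool = False
    inducer: str | None = None
    added_not_scored: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def _digraph(net: BooleanNetwork, undirected: bool) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for e in net.edges:
        g.add_edge(e.src, e.dst)
        if undirected:
            g.add_edge(e.dst, e.src)
    return g


def eccentricity(net: BooleanNetwork, node: str, undirected: bool = False) -> float:
    """Inverse of the longest shortest path from ``node`` to any reachable node.

    Unreachable targets are excluded; a node with no outgoing reachability
    returns 0.0.
    """
    if node not in net.nodes:
        raise NetworkError(f"node {node!r} not in network")
    g = _digraph(net, undirected)
    lengths = nx.single_source_shortest_path_length(g, node)
    lengths.pop(node, None)
    if not lengths:
        return 0.0
    return 1.0 / max(lengths.values())


def score_nodes(
    net: BooleanNetwork,
    log_base: float = math.e,
    undirected: bool = False,
) -> pd.DataFrame:
    """Score every node; returns a DataFrame indexed by node id.

    Columns: ``out_degree``, ``eccentricity``, ``rank_out_degree``,
    ``rank_eccentricity``, ``score`` where ``score = -log(R_OD + R_E)``.
    Rank 1 is the largest value of each metric; ties receive the mean of
    the tied rank positions (deterministic).
    """
    if not net.nodes:
        raise NetworkError("cannot score an empty network")
    g = _digraph(net, undirected)
    out_deg = {nid: 0 for nid in net.nodes}
    for e in net.edges:
        out_deg[e.src] += 1
    ecc = {}
    for nid in net.nodes:
        lengths = nx.single_source_shortest_path_length(g, nid)
        lengths.pop(nid, None)
        ecc[nid] = 1.0 / max(lengths.values()) if lengths else 0.0
    df = pd.DataFrame(
        {"out_degree": pd.Series(out_deg), "eccentricity": pd.Series(ecc)}
    ).loc[list(net.nodes)]
    df["rank_out_degree"] = df["out_degree"].rank(ascending=False, method="average")
    df["rank_eccentricity"] = df["eccentricity"].rank(ascending=False, method="average")
    rank_sum = df["rank_out_degree"] + df["rank_eccentricity"]
    df["score"] = -rank_sum.map(lambda r: math.log(r, log_base))
    return df


def select_signature(
    scores: pd.DataFrame,
    threshold: float = -2.5,
    inducer: str | None = None,
) -> Signature:
    """Select nodes with score >= threshold, sorted by descending score.

    If ``inducer`` is given and not already selected, it is appended to the
    signature (flagged as added-not-scored) — the convention used to clamp
    an external stimulus such as TGF-β1 into the phenotype space.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    selected = scores.loc[scores["score"] >= threshold].sort_values(
        by=["score"], ascending=False, kind="mergesort"
    )
    genes = list(selected.index)
    sig = Signature(genes, threshold)
    if inducer is not None:
        sig.inducer = inducer
        sig.includes_inducer = True
        if inducer not in genes:
            sig.genes.append(inducer)
            sig.added_not_scored.append(inducer)
    return sig
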