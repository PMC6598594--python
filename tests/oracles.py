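"""Independent reference implementations used to check the package.

Everything here is written from the rule definitions directly, without
using the package's simulation/graph code paths, so the tests compare two
independent routes to the same quantity.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def ref_node_update(net, values: dict, node: str) -> int:
    """Naive truth-table update of one node (MAJ tie-hold / AND)."""
    incoming = [(e.src, e.sign) for e in net.edges if e.dst == node]
    if not incoming:
        return values[node]
    if net.nodes[node].rule == "AND":
        return int(all(values[src] == 1 for src, _ in incoming))
    delta = sum(sign for src, sign in incoming if values[src] == 1)
    if delta > 0:
        return 1
    if delta < 0:
        return 0
    return values[node]


def ref_fixed_points(net) -> set[tuple[int, ...]]:
    """All fixed points by exhaustive enumeration over node-value tuples.

    Incoming edges are gathered once; each candidate state is then checked
    node by node against the plain rule definitions.
    """
    order = list(net.nodes)
    pos = {n: i for i, n in enumerate(order)}
    incoming = {n: [] for n in order}
    for e in net.edges:
        incoming[e.dst].append((pos[e.src], e.sign))
    rules = [net.nodes[n].rule for n in order]
    fps = set()
    for bits in itertools.product([0, 1], repeat=len(order)):
        stable = True
        for i, n in enumerate(order):
            inputs = incoming[n]
            if not inputs:
                continue  # input-free nodes hold
            if rules[i] == "AND":
                nxt = int(all(bits[j] == 1 for j, _ in inputs))
            else:
                delta = sum(sign for j, sign in inputs if bits[j] == 1)
                nxt = 1 if delta > 0 else (0 if delta < 0 else bits[i])
            if nxt != bits[i]:
                stable = False
                break
        if stable:
            fps.add(bits)
    return fps


def ref_components(net) -> list[frozenset]:
    """Weakly connected components via union-find on the undirected skeleton."""
    parent = {n: n for n in net.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in net.edges:
        ra, rb = find(e.src), find(e.dst)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in net.nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def ref_eccentricity(net, node: str) -> float:
    """1 / longest shortest directed distance, via a hand-rolled BFS."""
    adj: dict[str, list[str]] = {n: [] for n in net.nodes}
    for e in net.edges:
        adj[e.src].append(e.dst)
    dist = {node: 0}
    q = deque([node])
    while q:
        cur = q.popleft()
        for nxt in adj[cur]:
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                q.append(nxt)
    dist.pop(node)
    return 1.0 / max(dist.values()) if dist else 0.0


def ref_jnd(test, ref) -> float:
    """Jaccard dissimilarity by direct position counting."""
    both_one = disagree = 0
    for a, b in zip(test, ref, strict=True):
        if a == 1 and b == 1:
            both_one += 1
        elif a != b:
            disagree += 1
    den = both_one + disagree
    return disagree / den if den else 0.0


def ref_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic chain via eigen-decomposition."""
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    s = np.real(v[:, i])
    return s / s.sum()


def ref_single_gene_pairs(patterns: dict, gene_pos: int) -> set[tuple]:
    """All-pairs scan for patterns differing only at gene_pos."""
    out = set()
    items = list(patterns.items())
    for (ia, a), (ib, b) in itertools.combinations(items, 2):
        diffs = [k for k in range(len(a)) if a[k] != b[k]]
        if diffs == [gene_pos]:
            out.add(tuple(sorted((ia, ib))))
    return out
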