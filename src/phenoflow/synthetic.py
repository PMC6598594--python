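"""Synthetic fixtures: toy KGML pathways, random Boolean networks, planted
attractor structures, expression tables and small Markov chains.

Everything here is deterministic under its seed and exists so the full
pipeline can be exercised without any external download.  No attempt is
made to synthesize biologically realistic pathway content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtmc_builder import PhenotypeDTMC, PhenotypeState
from .network import AND, MAJ, BooleanNetwork

__all__ = [
    "FixtureSpec",
    "random_boolean_network",
    "planted_attractor_network",
    "toy_kgml",
    "synthetic_expression_table",
    "random_chain",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random Boolean-network fixture."""

    n_nodes: int = 12
    edge_density: float = 0.1
    inhibition_fraction: float = 0.25
    n_complexes: int = 0
    planted_hubs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.edge_density, self.inhibition_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")


def random_boolean_network(spec: FixtureSpec) -> BooleanNetwork:
    """Erdős–Rényi-style directed signed network.

    Each ordered pair gets an edge with probability ``edge_density``
    (inhibiting with probability ``inhibition_fraction``).  Complexes are
    AND nodes fed by random gene pairs.  Each planted hub receives
    activating out-edges until its out-degree is at least 10x the median
    out-degree (capped at n−1), guaranteeing it tops the out-degree
    ranking.
    """
    rng = np.random.default_rng(spec.seed)
    net = BooleanNetwork()
    names = [f"g{i}" for i in range(spec.n_nodes)]
    for n in names:
        net.add_node(n, MAJ)
    existing: set[tuple[str, str]] = set()
    if spec.edge_density > 0:
        for i, j in itertools.permutations(range(spec.n_nodes), 2):
            if rng.random() < spec.edge_density:
                sign = -1 if rng.random() < spec.inhibition_fraction else 1
                net.add_edge(names[i], names[j], sign)
                existing.add((names[i], names[j]))
    for c in range(spec.n_complexes):
        if spec.n_nodes < 2:
            break
        members = rng.choice(spec.n_nodes, size=2, replace=False)
        cid = f"cplx{c}:" + "+".join(names[m] for m in sorted(members))
        net.add_node(cid, AND)
        for m in members:
            net.add_edge(names[m], cid, 1)
    if spec.planted_hubs:
        out_deg = {n: 0 for n in names}
        for e in net.edges:
            if e.src in out_deg:
                out_deg[e.src] += 1
        median_od = float(np.median([out_deg[n] for n in names]))
        target = min(spec.n_nodes - 1, max(10, int(np.ceil(10 * max(median_od, 1.0)))))
        hubs = [names[h] for h in rng.choice(spec.n_nodes, size=spec.planted_hubs, replace=False)]
        for hub in hubs:
            candidates = [n for n in names if n != hub and (hub, n) not in existing]
            rng.shuffle(candidates)
            while out_deg[hub] < target and candidates:
                tgt = candidates.pop()
                net.add_edge(hub, tgt, 1)
                existing.add((hub, tgt))
                out_deg[hub] += 1
        net.meta["hubs"] = hubs
    net.validate()
    return net


def planted_attractor_network(
    k_basins: int, seed: int = 0
) -> tuple[BooleanNetwork, list[np.ndarray]]:
    """Network whose fixed points are known by construction.

    Built from ``k`` disjoint self-reinforcing 3-node loops (each node
    activated by the other two, so a loop is bistable: all-ON or all-OFF)
    plus a ring of single inter-loop inhibitions into one designated node
    per loop.  Under the MAJ tie-hold rule the fixed points are exactly the
    2^k combinations of loop ON/OFF states, returned alongside the network
    in the network's node order.
    """
    if not 1 <= k_basins <= 4:
        raise ValueError("k_basins must be in 1..4")
    net = BooleanNetwork()
    for b in range(k_basins):
        members = [f"L{b}n{j}" for j in range(3)]
        for m in members:
            net.add_node(m, MAJ)
        for x, y in itertools.permutations(members, 2):
            net.add_edge(x, y, 1)
    if k_basins > 1:
        for b in range(k_basins):
            net.add_edge(f"L{b}n0", f"L{(b + 1) % k_basins}n0", -1)
    net.validate()
    order = net.node_order
    fixed_points = []
    for combo in itertools.product([0, 1], repeat=k_basins):
        state = np.array(
            [combo[int(n[1])] for n in order], dtype=np.uint8
        )
        fixed_points.append(state)
    return net, fixed_points


def toy_kgml(
    pathway_id: str = "synthetic01",
    include_unmapped: bool = False,
    gene_prefix: str = "syn",
    offset: int = 0,
) -> str:
    """A valid KGML document exercising every mapped relation subtype.

    Contains gene entries, a <group> complex, and one relation per
    interaction type (activation, expression, inhibition,
    binding/association, complex, dissociation, missing interaction,
    remove).  With ``include_unmapped`` an extra "state change" relation
    exercises the unmapped path.  ``offset`` shifts gene numbering so that
    several toy pathways overlap partially when merged.
    """
    g = [f"{gene_prefix}:G{offset + i}" for i in range(1, 9)]
    entries = "\n".join(
        f'  <entry id="{i + 1}" name="{g[i]}" type="gene">\n'
        f'    <graphics name="G{offset + i + 1}"/>\n'
        f"  </entry>"
        for i in range(8)
    )
    group = (
        '  <entry id="20" type="group">\n'
        '    <component id="4"/>\n'
        '    <component id="6"/>\n'
        "  </entry>"
    )
    relations = [
        ('1', '2', 'PPrel', 'activation'),
        ('1', '4', 'GErel', 'expression'),
        ('3', '2', 'PPrel', 'inhibition'),
        ('2', '5', 'PPrel', 'binding/association'),
        ('4', '6', 'PPrel', 'complex'),
        ('5', '7', 'PPrel', 'dissociation'),
        ('7', '8', 'PPrel', 'missing interaction'),
        ('8', '1', 'PPrel', 'remove'),
        ('3', '20', 'PPrel', 'inhibition'),  # regulation targeting a group
    ]
    if include_unmapped:
        relations.append(('6', '8', 'PPrel', 'state change'))
    rel_xml = "\n".join(
        f'  <relation entry1="{e1}" entry2="{e2}" type="{t}">\n'
        f'    <subtype name="{st}" value="--"/>\n'
        f"  </relation>"
        for e1, e2, t, st in relations
    )
    return (
        '<?xml version="1.0"?>\n'
        f'<pathway name="path:{pathway_id}" org="syn" number="1" title="{pathway_id}">\n'
        f"{entries}\n{group}\n{rel_xml}\n</pathway>\n"
    )


def synthetic_expression_table(
    genes,
    profile: str = "graded",
    seed: int = 0,
    base: float = 100.0,
) -> pd.DataFrame:
    """(gene_id, baseMean) table emulating a normalized bulk-RNA-seq summary.

    Profiles: ``graded`` halves the baseMean at each successive gene
    (strictly ordered, so prevalence targets are exactly checkable);
    ``uniform`` gives every gene the same value; ``sparse`` is graded with
    the last gene silenced (baseMean 0); ``random`` draws log-uniform
    values under the seed.
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)
    if profile == "graded":
        values = [base * 0.5**i for i in range(len(genes))]
    elif profile == "uniform":
        values = [base] * len(genes)
    elif profile == "sparse":
        values = [base * 0.5**i for i in range(len(genes))]
        if values:
            values[-1] = 0.0
    elif profile == "random":
        values = list(base * 10 ** rng.uniform(-2, 0, size=len(genes)))
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return pd.DataFrame({"gene_id": genes, "baseMean": values})


def random_chain(
    n_genes: int = 5,
    n_states: int | None = None,
    seed: int = 0,
    all_patterns: bool = False,
    concentration: float = 1.0,
) -> PhenotypeDTMC:
    """A small random phenotype chain for simulation tests.

    States carry distinct random patterns over ``n_genes`` signature genes
    (or all 2^n patterns with ``all_patterns``); rows of the transition
    matrix are Dirichlet draws, so the chain is ergodic with probability 1.
    """
    rng = np.random.default_rng(seed)
    if all_patterns:
        patterns = list(itertools.product([0, 1], repeat=n_genes))
    else:
        n_states = n_states or min(2**n_genes, 6)
        if n_states > 2**n_genes:
            raise ValueError("more states than distinct patterns")
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < n_states:
            chosen.add(tuple(int(v) for v in rng.integers(0, 2, size=n_genes)))
        patterns = sorted(chosen)
    k = len(patterns)
    P = rng.dirichlet(np.full(k, concentration), size=k)
    states = [
        PhenotypeState(i, p, [np.array(p, dtype=np.uint8)], basin_weight=1)
        for i, p in enumerate(patterns)
    ]
    genes = [f"g{i}" for i in range(n_genes)]
    arr = np.array(patterns, dtype=np.uint8)
    distances = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
    dtmc = PhenotypeDTMC(
        states=states, P=P, signature_genes=genes, distances=distances
    )
    dtmc.validate()
    return dtmc
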