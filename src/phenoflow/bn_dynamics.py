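"""Constrained-asynchronous Boolean dynamics and fixed-point (attractor) search.

Update scheme
-------------
Each *sweep* draws a fresh uniform random permutation of the nodes and
updates them sequentially, each update seeing the latest values.  This is
akin to asynchronous update but constrains every node to be revised within
the same iteration; single-state attractors (fixed points) are unaffected
by the ordering, because a fixed point requires every node individually to
reproduce its own value.

Node rules:

* ``AND`` — ON iff all inputs are ON;
* ``MAJ`` — let Δ = (# active activating inputs) − (# active inhibiting
  inputs); Δ>0 → ON, Δ<0 → OFF, Δ=0 → hold the current value.  An OFF
  inhibitor exerts no repression: only active inputs are counted.

Input-free nodes hold their initial value, which is what lets an external
inducer (e.g. TGF-β1) act as a clamped input.

States are numpy ``uint8`` arrays in the network's canonical node order;
helpers convert to/from ``{node_id: 0/1}`` mappings and bit-strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import AND, MAJ, BooleanNetwork, NetworkError

__all__ = [
    "CompiledNetwork",
    "SimulationResult",
    "AttractorCampaignResult",
    "compile_network",
    "update_node",
    "sweep",
    "run_to_attractor",
    "random_initial_state",
    "perturb_state",
    "attractor_campaign",
    "enumerate_fixed_points",
    "state_to_bits",
    "bits_to_state",
]

DEFAULT_MAX_ITER = 100_000  # reference stopping criterion for one simulation
DEFAULT_P_GRID = tuple(round(0.05 * i, 2) for i in range(21))  # 0%..100% in 5% steps

MAJ_TIE_HOLD = "hold"
MAJ_TIE_OFF = "off"


class CompiledNetwork:
    """Index-based view of a :class:`BooleanNetwork` for fast simulation."""

    def __init__(self, net: BooleanNetwork, tie_rule: str = MAJ_TIE_HOLD):
        if tie_rule not in (MAJ_TIE_HOLD, MAJ_TIE_OFF):
            raise ValueError(f"unknown MAJ tie rule {tie_rule!r}")
        net.validate()
        self.network = net
        self.tie_rule = tie_rule
        self.nodes: list[str] = list(net.nodes)
        self.index: dict[str, int] = {nid: i for i, nid in enumerate(self.nodes)}
        self.is_and = np.array(
            [net.nodes[nid].rule == AND for nid in self.nodes], dtype=bool
        )
        act: list[list[int]] = [[] for _ in self.nodes]
        inh: list[list[int]] = [[] for _ in self.nodes]
        for e in net.edges:
            (act if e.sign == 1 else inh)[self.index[e.dst]].append(self.index[e.src])
        self.act_in = [np.array(a, dtype=np.intp) for a in act]
        self.inh_in = [np.array(a, dtype=np.intp) for a in inh]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    # -- single-node update --------------------------------------------------

    def update_value(self, state: np.ndarray, i: int) -> int:
        act = self.act_in[i]
        inh = self.inh_in[i]
        if act.size == 0 and inh.size == 0:
            return int(state[i])
        if self.is_and[i]:
            return int(state[act].all())
        delta = int(state[act].sum()) - int(state[inh].sum())
        if delta > 0:
            return 1
        if delta < 0:
            return 0
        return int(state[i]) if self.tie_rule == MAJ_TIE_HOLD else 0

    # -- state helpers ---------------------------------------------------------

    def state_from_dict(self, values: Mapping[str, int]) -> np.ndarray:
        missing = [n for n in self.nodes if n not in values]
        if missing:
            raise NetworkError(f"state missing nodes: {missing[:5]}")
        return np.array([int(values[n]) for n in self.nodes], dtype=np.uint8)

    def state_to_dict(self, state: np.ndarray) -> dict[str, int]:
        return {n: int(v) for n, v in zip(self.nodes, state)}


def compile_network(net: BooleanNetwork | CompiledNetwork, **kw) -> CompiledNetwork:
    if isinstance(net, CompiledNetwork):
        return net
    return CompiledNetwork(net, **kw)


def state_to_bits(state: Sequence[int]) -> str:
    return "".join(str(int(v)) for v in state)


def bits_to_state(bits: str) -> np.ndarray:
    return np.array([int(c) for c in bits], dtype=np.uint8)


@dataclass
class SimulationResult:
    end_state: np.ndarray
    converged: bool
    iterations: int
    trajectory_length: int

    def __post_init__(self) -> None:
        self.end_state = np.asarray(self.end_state, dtype=np.uint8)


@dataclass
class AttractorCampaignResult:
    """Deduplicated fixed points with basin-size estimates."""

    attractors: list[tuple[np.ndarray, int]]
    n_sims: int
    n_converged: int
    node_order: list[str] = field(default_factory=list)

    @property
    def n_nonconverged(self) -> int:
        return self.n_sims - self.n_converged


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def update_node(
    net: BooleanNetwork | CompiledNetwork,
    state: Mapping[str, int] | np.ndarray,
    node: str,
) -> int:
    """Value of ``node`` after one rule application against ``state``."""
    cn = compile_network(net)
    if node not in cn.index:
        raise NetworkError(f"node {node!r} not in network")
    arr = state if isinstance(state, np.ndarray) else cn.state_from_dict(state)
    return cn.update_value(arr, cn.index[node])


def sweep(
    net: BooleanNetwork | CompiledNetwork,
    state: np.ndarray | Mapping[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One constrained-asynchronous iteration: every node updated exactly
    once, sequentially, in a fresh uniform random order."""
    cn = compile_network(net)
    s = (
        state.astype(np.uint8, copy=True)
        if isinstance(state, np.ndarray)
        else cn.state_from_dict(state)
    )
    for i in rng.permutation(cn.n_nodes):
        s[i] = cn.update_value(s, i)
    return s


def run_to_attractor(
    net: BooleanNetwork | CompiledNetwork,
    init: np.ndarray | Mapping[str, int],
    max_iter: int = DEFAULT_MAX_ITER,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Iterate sweeps until one leaves the state unchanged, or ``max_iter``.

    ``iterations`` counts the sweeps performed, including the final
    confirming sweep; a fixed initial state converges at iteration 1.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    cn = compile_network(net)
    s = (
        init.astype(np.uint8, copy=True)
        if isinstance(init, np.ndarray)
        else cn.state_from_dict(init)
    )
    for it in range(1, max_iter + 1):
        nxt = sweep(cn, s, rng)
        if np.array_equal(nxt, s):
            return SimulationResult(nxt, True, it, it + 1)
        s = nxt
    return SimulationResult(s, False, max_iter, max_iter + 1)


def random_initial_state(
    net: BooleanNetwork | CompiledNetwork,
    p_active: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Each node independently ON with probability ``p_active``."""
    if not 0.0 <= p_active <= 1.0:
        raise ValueError("p_active must be in [0, 1]")
    cn = compile_network(net)
    return (rng.random(cn.n_nodes) < p_active).astype(np.uint8)


def perturb_state(
    state: np.ndarray, flip_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each node's value independently with probability ``flip_prob``."""
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    arr = np.asarray(state, dtype=np.uint8)
    flips = rng.random(arr.size) < flip_prob
    return np.where(flips, 1 - arr, arr).astype(np.uint8)


def attractor_campaign(
    net: BooleanNetwork | CompiledNetwork,
    n_sims: int,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    max_iter: int = DEFAULT_MAX_ITER,
    rng: np.random.Generator | None = None,
) -> AttractorCampaignResult:
    """Fixed-point search from random initial conditions.

    ``n_sims`` runs are split evenly across the activation-probability grid
    (default 0–100% in 5% steps); remainder runs go to p = 0.5 (or the grid
    midpoint).  Converged end states are deduplicated with occurrence
    counts — empirical basin-size estimates — sorted descending.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    cn = compile_network(net)
    per_p = n_sims // len(p_grid)
    remainder = n_sims - per_p * len(p_grid)
    mid = 0.5 if 0.5 in p_grid else p_grid[len(p_grid) // 2]
    counts: dict[bytes, int] = {}
    states: dict[bytes, np.ndarray] = {}
    n_converged = 0
    for p in p_grid:
        runs = per_p + (remainder if p == mid else 0)
        for _ in range(runs):
            init = random_initial_state(cn, p, rng)
            res = run_to_attractor(cn, init, max_iter, rng)
            if res.converged:
                n_converged += 1
                key = res.end_state.tobytes()
                if key not in counts:
                    counts[key] = 0
                    states[key] = res.end_state
                counts[key] += 1
    attractors = sorted(
        ((states[k], c) for k, c in counts.items()),
        key=lambda kv: (-kv[1], state_to_bits(kv[0])),
    )
    return AttractorCampaignResult(attractors, n_sims, n_converged, list(cn.nodes))


def enumerate_fixed_points(net: BooleanNetwork | CompiledNetwork) -> list[np.ndarray]:
    """Exhaustive fixed-point enumeration over all 2^n states (n <= ~20).

    A state is a fixed point iff every node individually reproduces its own
    value — order-independent, so this is exact for the sweep scheme.
    """
    cn = compile_network(net)
    n = cn.n_nodes
    if n > 22:
        raise ValueError(f"exhaustive enumeration infeasible for n={n}")
    codes = np.arange(2**n, dtype=np.int64)
    # bit i of the code is node i's value
    states = ((codes[:, None] >> np.arange(n)) & 1).astype(np.uint8)
    stable = np.ones(2**n, dtype=bool)
    for i in range(n):
        act, inh = cn.act_in[i], cn.inh_in[i]
        cur = states[:, i]
        if act.size == 0 and inh.size == 0:
            continue  # input-free nodes always hold
        if cn.is_and[i]:
            nxt = states[:, act].all(axis=1).astype(np.uint8)
        else:
            delta = states[:, act].sum(axis=1).astype(int) - states[:, inh].sum(
                axis=1
            ).astype(int)
            if cn.tie_rule == MAJ_TIE_HOLD:
                nxt = np.where(delta > 0, 1, np.where(delta < 0, 0, cur)).astype(
                    np.uint8
                )
            else:
                nxt = (delta > 0).astype(np.uint8)
        stable &= nxt == cur
    return [states[j].copy() for j in np.nonzero(stable)[0]]
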