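"""Collapse attractors into signature-defined phenotypes and build the DTMC.

Attractors (full Boolean fixed points) are grouped by their projection onto
the signature genes; each distinct pattern is a *phenotype state* of a
discrete-time Markov chain.  Transitions are estimated by perturbing each
phenotype's representative attractors (flipping each gene with a small
probability, escalated until the system leaves the source basin) and
recording the destination.  The transition probability applies a
biological-plausibility correction to the raw frequencies::

    raw_ij = (N_ij / N_i) * 1 / (d_ij * I_ij)

where ``N_ij`` counts recorded i→j transitions, ``N_i = Σ_j N_ij``,
``d_ij`` is the Hamming distance between the signature patterns and
``I_ij`` the mean number of sweeps of the recorded i→j runs — the
correction favors transitions between similar phenotypes and shorter
simulations.  Rows are then renormalized to sum to one so the chain
conserves population mass; sources with no recorded exit become explicit
absorbing states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bn_dynamics import (
    DEFAULT_MAX_ITER,
    CompiledNetwork,
    compile_network,
    perturb_state,
    run_to_attractor,
    state_to_bits,
)
from .network import BooleanNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeState",
    "PhenotypeDTMC",
    "TransitionRecord",
    "merge_attractors",
    "snap_to_known",
    "transition_campaign",
    "build_matrix",
]


@dataclass
class PhenotypeState:
    """One DTMC node: a signature-gene expression pattern."""

    state_id: int
    pattern: tuple[int, ...]
    representative_full_states: list[np.ndarray] = field(default_factory=list)
    basin_weight: int = 0

    def expresses(self, gene_index: int) -> bool:
        return bool(self.pattern[gene_index])


@dataclass
class PhenotypeDTMC:
    """Phenotype states plus the row-stochastic transition matrix.

    ``P[i, j]`` is the probability of moving from state i to state j in one
    iteration (row = source).  ``counts``/``totals``/``distances``/
    ``mean_lengths`` retain the raw ingredients of the correction; they may
    be ``None`` for synthetic chains.
    """

    states: list[PhenotypeState]
    P: np.ndarray
    signature_genes: list[str]
    counts: np.ndarray | None = None
    totals: np.ndarray | None = None
    distances: np.ndarray | None = None
    mean_lengths: np.ndarray | None = None
    absorbing: list[int] = field(default_factory=list)
    build_log: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def patterns(self) -> list[tuple[int, ...]]:
        return [s.pattern for s in self.states]

    def gene_index(self, gene: str) -> int:
        return self.signature_genes.index(gene)

    def validate(self) -> None:
        P = self.P
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if (P < 0).any():
            raise ValueError("negative transition probability")
        rows = P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError(f"rows not stochastic: {rows}")


@dataclass
class TransitionRecord:
    """One perturbation run; ``dest is None`` marks an escalation failure."""

    source: int
    dest: int | None
    iterations: int
    escalations: int
    n_snapped: int = 0


def _signature_indices(compiled: CompiledNetwork, signature_genes: Sequence[str]) -> np.ndarray:
    missing = [g for g in signature_genes if g not in compiled.index]
    if missing:
        raise KeyError(f"signature genes absent from network: {missing}")
    return np.array([compiled.index[g] for g in signature_genes], dtype=np.intp)


def merge_attractors(
    attractors: Sequence[tuple[np.ndarray, int]],
    signature_genes: Sequence[str],
    net: BooleanNetwork | CompiledNetwork,
) -> list[PhenotypeState]:
    """Group full attractors by exact signature-gene pattern.

    ``basin_weight`` sums the attractors' occurrence counts; state ids are
    assigned in descending basin weight (patterns break ties).
    """
    if not attractors:
        raise ValueError("no attractors to merge")
    cn = compile_network(net)
    idx = _signature_indices(cn, signature_genes)
    groups: dict[tuple[int, ...], PhenotypeState] = {}
    for state, count in attractors:
        arr = np.asarray(state, dtype=np.uint8)
        pattern = tuple(int(v) for v in arr[idx])
        ps = groups.get(pattern)
        if ps is None:
            ps = groups[pattern] = PhenotypeState(-1, pattern)
        ps.basin_weight += int(count)
        if not any(np.array_equal(arr, r) for r in ps.representative_full_states):
            ps.representative_full_states.append(arr.copy())
    ordered = sorted(groups.values(), key=lambda s: (-s.basin_weight, s.pattern))
    for i, ps in enumerate(ordered):
        ps.state_id = i
    return ordered


def snap_to_known(
    pattern: Sequence[int], states: Sequence[PhenotypeState]
) -> tuple[int, int]:
    """Closest known phenotype by signature Hamming distance.

    Ties go to the larger basin weight, then the smaller state id.  Returns
    ``(state_id, n_changed)`` where ``n_changed`` is the distance (0 for an
    exact match).
    """
    if not states:
        raise ValueError("no known states to snap to")
    p = np.asarray(pattern, dtype=np.uint8)
    best: tuple[int, int, int] | None = None  # (dist, -basin, state_id)
    for s in states:
        d = int(np.count_nonzero(p != np.asarray(s.pattern, dtype=np.uint8)))
        key = (d, -s.basin_weight, s.state_id)
        if best is None or key < best:
            best = key
    return best[2], best[0]


def transition_campaign(
    net: BooleanNetwork | CompiledNetwork,
    states: Sequence[PhenotypeState],
    signature_genes: Sequence[str],
    n_sims: int,
    flip_start: float = 0.05,
    flip_step: float = 0.05,
    max_iter: int = DEFAULT_MAX_ITER,
    rng: np.random.Generator | None = None,
) -> list[TransitionRecord]:
    """Perturb each phenotype until it exits its own basin.

    Runs are distributed evenly over source states.  Each run samples one
    representative full attractor of the source, flips every gene with the
    current probability and simulates to an attractor; if the destination
    phenotype equals the source (or the run does not converge) the flip
    probability escalates by ``flip_step`` and the run retries, failing
    once the probability exceeds 100%.  End states whose pattern is not
    among the known phenotypes are snapped to the closest one.
    """
    if not states:
        raise ValueError("transition campaign needs at least one state")
    rng = np.random.default_rng() if rng is None else rng
    cn = compile_network(net)
    idx = _signature_indices(cn, signature_genes)
    k = len(states)
    per_state = n_sims // k
    remainder = n_sims - per_state * k
    records: list[TransitionRecord] = []
    for src in states:
        runs = per_state + (1 if src.state_id < remainder else 0)
        reps = src.representative_full_states
        if not reps:
            raise ValueError(f"state {src.state_id} has no representative attractor")
        for _ in range(runs):
            flip = flip_start
            escalations = 0
            while True:
                rep = reps[rng.integers(len(reps))]
                init = perturb_state(rep, flip, rng)
                res = run_to_attractor(cn, init, max_iter, rng)
                if res.converged:
                    pattern = tuple(int(v) for v in res.end_state[idx])
                    dest, n_changed = snap_to_known(pattern, states)
                    if dest != src.state_id:
                        records.append(
                            TransitionRecord(
                                src.state_id, dest, res.iterations, escalations, n_changed
                            )
                        )
                        break
                flip = round(flip + flip_step, 10)
                escalations += 1
                if flip > 1.0 + 1e-9:
                    records.append(
                        TransitionRecord(src.state_id, None, res.iterations, escalations)
                    )
                    break
    return records


def build_matrix(
    records: Sequence[TransitionRecord],
    states: Sequence[PhenotypeState],
    signature_genes: Sequence[str] | None = None,
) -> PhenotypeDTMC:
    """Assemble the corrected, row-normalized transition matrix.

    For i != j: ``raw_ij = (N_ij / N_i) / (d_ij * I_ij)``; each row is then
    renormalized to sum to 1.  Sources with zero successful exits become
    absorbing (p_ii = 1) and are listed in ``dtmc.absorbing``.  The snap
    fraction (runs whose end pattern had to be modified) and failure count
    are reported in ``build_log``.
    """
    k = len(states)
    if k == 0:
        raise ValueError("no states")
    genes = list(signature_genes) if signature_genes is not None else [
        f"g{i}" for i in range(len(states[0].pattern))
    ]
    patterns = np.array([s.pattern for s in states], dtype=np.uint8)
    distances = (patterns[:, None, :] != patterns[None, :, :]).sum(axis=2).astype(float)
    counts = np.zeros((k, k), dtype=float)
    iter_sums = np.zeros((k, k), dtype=float)
    n_failures = 0
    n_snapped = 0
    n_success = 0
    for r in records:
        if r.dest is None:
            n_failures += 1
            continue
        n_success += 1
        if r.n_snapped > 0:
            n_snapped += 1
        counts[r.source, r.dest] += 1
        iter_sums[r.source, r.dest] += r.iterations
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lengths = np.where(counts > 0, iter_sums / np.maximum(counts, 1), 0.0)
    totals = counts.sum(axis=1)
    P = np.zeros((k, k), dtype=float)
    absorbing: list[int] = []
    for i in range(k):
        if totals[i] == 0:
            P[i, i] = 1.0
            absorbing.append(i)
            continue
        raw = np.zeros(k)
        for j in range(k):
            if i == j or counts[i, j] == 0:
                continue
            if distances[i, j] == 0:
                raise RuntimeError(
                    f"recorded transition {i}->{j} between identical patterns"
                )
            raw[j] = (counts[i, j] / totals[i]) / (distances[i, j] * mean_lengths[i, j])
        P[i] = raw / raw.sum()
    snap_fraction = n_snapped / n_success if n_success else 0.0
    if absorbing:
        logger.info("absorbing states (no recorded exits): %s", absorbing)
    logger.info(
        "build_matrix: %d transitions, %d failures, snap fraction %.3f",
        n_success, n_failures, snap_fraction,
    )
    dtmc = PhenotypeDTMC(
        states=list(states),
        P=P,
        signature_genes=genes,
        counts=counts,
        totals=totals,
        distances=distances,
        mean_lengths=mean_lengths,
        absorbing=absorbing,
        build_log={
            "n_records": len(records),
            "n_success": n_success,
            "n_failures": n_failures,
            "snap_fraction": snap_fraction,
        },
    )
    dtmc.validate()
    return dtmc


# ---------------------------------------------------------------------------
# Serialization (JSON dialect used by the pipeline artifacts)
# ---------------------------------------------------------------------------

def dtmc_to_dict(dtmc: PhenotypeDTMC) -> dict:
    return {
        "signature_genes": list(dtmc.signature_genes),
        "states": [
            {
                "id": s.state_id,
                "pattern": state_to_bits(s.pattern),
                "basin_weight": s.basin_weight,
                "representatives": [
                    state_to_bits(r) for r in s.representative_full_states
                ],
            }
            for s in dtmc.states
        ],
        "P": dtmc.P.tolist(),
        "counts": None if dtmc.counts is None else dtmc.counts.tolist(),
        "distances": None if dtmc.distances is None else dtmc.distances.tolist(),
        "mean_lengths": None
        if dtmc.mean_lengths is None
        else dtmc.mean_lengths.tolist(),
        "absorbing": list(dtmc.absorbing),
        "build_log": dict(dtmc.build_log),
    }


def dtmc_from_dict(data: dict) -> PhenotypeDTMC:
    states = [
        PhenotypeState(
            state_id=s["id"],
            pattern=tuple(int(c) for c in s["pattern"]),
            representative_full_states=[
                np.array([int(c) for c in r], dtype=np.uint8)
                for r in s.get("representatives", [])
            ],
            basin_weight=s.get("basin_weight", 0),
        )
        for s in data["states"]
    ]
    dtmc = PhenotypeDTMC(
        states=states,
        P=np.array(data["P"], dtype=float),
        signature_genes=list(data["signature_genes"]),
        counts=None if data.get("counts") is None else np.array(data["counts"]),
        totals=None
        if data.get("counts") is None
        else np.array(data["counts"]).sum(axis=1),
        distances=None if data.get("distances") is None else np.array(data["distances"]),
        mean_lengths=None
        if data.get("mean_lengths") is None
        else np.array(data["mean_lengths"]),
        absorbing=list(data.get("absorbing", [])),
        build_log=dict(data.get("build_log", {})),
    )
    dtmc.validate()
    return dtmc
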