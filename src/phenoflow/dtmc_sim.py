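"""Population-level simulation of the phenotype DTMC.

A population is a *prevalence vector* ``s`` — the fraction of cells in each
phenotype state, summing to one.  One iteration moves mass along the
recorded transitions::

    s(t+1) = P^T · s(t)

(``P`` is stored row-stochastic, row = source, so the transpose is what
conserves total mass).  Virtual initial populations are constructed to be
coherent with a bulk expression summary: each signature gene's *marginal*
(the population fraction expressing it) is matched to a target derived
from the normalized mean read counts (baseMean), via randomized Dirichlet
initialization followed by multiplicative marginal fitting (IPF-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dtmc_builder import PhenotypeDTMC

__all__ = [
    "PopulationTrajectory",
    "FeasibilityError",
    "step",
    "simulate",
    "read_expression_table",
    "marker_prevalence_targets",
    "sample_virtual_population",
]


class FeasibilityError(RuntimeError):
    """Marginal targets could not be met on the eligible state set."""


@dataclass
class PopulationTrajectory:
    """Time series of prevalence vectors plus chain metadata.

    ``prevalence`` has shape (n_iterations + 1, n_states); row 0 is the
    initial condition.  Each row sums to 1.
    """

    prevalence: np.ndarray
    signature_genes: list[str]
    patterns: list[tuple[int, ...]]
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.prevalence.shape[0] - 1

    @property
    def n_states(self) -> int:
        return self.prevalence.shape[1]

    def gene_prevalence(self, gene: str, t: int) -> float:
        """Fraction of the population expressing ``gene`` at iteration t."""
        gi = self.signature_genes.index(gene)
        mask = np.array([p[gi] for p in self.patterns], dtype=bool)
        return float(self.prevalence[t, mask].sum())


def step(dtmc: PhenotypeDTMC, s: np.ndarray) -> np.ndarray:
    """One DTMC iteration; mass flows along recorded source→destination
    transitions and the result is renormalized within 1e-12."""
    s = np.asarray(s, dtype=float)
    if s.shape != (dtmc.n_states,):
        raise ValueError(
            f"prevalence vector length {s.shape} does not match {dtmc.n_states} states"
        )
    out = dtmc.P.T @ s
    total = out.sum()
    if total <= 0:
        raise ValueError("population mass vanished")
    return out / total


def simulate(
    dtmc: PhenotypeDTMC,
    s0: np.ndarray,
    max_steps: int = 1000,
    tol: float = 1e-9,
) -> PopulationTrajectory:
    """Iterate :func:`step` until ``‖s(t+1) − s(t)‖_∞ < tol`` or ``max_steps``."""
    s = np.asarray(s0, dtype=float)
    if not np.isclose(s.sum(), 1.0, atol=1e-9):
        raise ValueError("initial prevalence vector must sum to 1")
    traj = [s.copy()]
    converged = False
    for _ in range(max_steps):
        nxt = step(dtmc, s)
        traj.append(nxt.copy())
        if np.max(np.abs(nxt - s)) < tol:
            converged = True
            s = nxt
            break
        s = nxt
    return PopulationTrajectory(
        prevalence=np.array(traj),
        signature_genes=list(dtmc.signature_genes),
        patterns=dtmc.patterns(),
        converged=converged,
        meta={"tol": tol, "max_steps": max_steps},
    )


# ---------------------------------------------------------------------------
# Virtual populations from expression summaries
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a (gene_id, baseMean) table from TSV/CSV."""
    p = Path(path)
    sep = "," if p.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(p, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id", df.columns[0])
    bm_col = cols.get("basemean", df.columns[1])
    out = df[[gene_col, bm_col]].rename(columns={gene_col: "gene_id", bm_col: "baseMean"})
    if (out["baseMean"] < 0).any():
        raise ValueError("baseMean values must be nonnegative")
    return out


def marker_prevalence_targets(
    expr: pd.DataFrame,
    genes: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Target expressing-fractions for each marker from baseMean ratios.

    The gene with the highest baseMean is assigned a random prevalence
    p* ~ Uniform(0.5, 1.0); every other gene g gets
    ``p* · baseMean_g / baseMean_max`` (clipped to [0, 1]).
    """
    table = dict(zip(expr["gene_id"], expr["baseMean"]))
    missing = [g for g in genes if g not in table]
    if missing:
        raise KeyError(f"expression table missing genes: {missing}")
    bm = np.array([float(table[g]) for g in genes])
    bm_max = bm.max()
    if bm_max <= 0:
        raise ValueError("max baseMean must be positive")
    p_star = rng.uniform(0.5, 1.0)
    targets = np.clip(p_star * bm / bm_max, 0.0, 1.0)
    return {g: float(t) for g, t in zip(genes, targets)}


def _eligible_mask(
    dtmc: PhenotypeDTMC,
    constraint: Mapping[str, int] | Callable[[tuple[int, ...]], bool] | None,
) -> np.ndarray:
    if constraint is None:
        return np.ones(dtmc.n_states, dtype=bool)
    if callable(constraint):
        return np.array([bool(constraint(p)) for p in dtmc.patterns()], dtype=bool)
    idx = {g: dtmc.gene_index(g) for g in constraint}
    return np.array(
        [all(p[idx[g]] == v for g, v in constraint.items()) for p in dtmc.patterns()],
        dtype=bool,
    )


def sample_virtual_population(
    dtmc: PhenotypeDTMC,
    targets: Mapping[str, float],
    constraint: Mapping[str, int] | Callable[[tuple[int, ...]], bool] | None = None,
    tol: float = 0.05,
    max_tries: int = 50,
    rng: np.random.Generator | None = None,
    max_ipf_iter: int = 500,
) -> np.ndarray:
    """One prevalence vector whose marker marginals match the targets.

    Supported only on states satisfying ``constraint`` (e.g. inducer ON).
    Initialization is a Dirichlet draw over eligible states, followed by
    multiplicative marginal fitting: each gene's expressing/non-expressing
    mass is rescaled toward its target, cycling until every marginal is
    within ``tol`` (absolute).  After ``max_tries`` rejected restarts a
    :class:`FeasibilityError` is raised.
    """
    rng = np.random.default_rng() if rng is None else rng
    mask = _eligible_mask(dtmc, constraint)
    if not mask.any():
        raise FeasibilityError("no eligible states under the constraint")
    elig = np.nonzero(mask)[0]
    genes = list(targets)
    gidx = [dtmc.gene_index(g) for g in genes]
    patterns = np.array(dtmc.patterns(), dtype=np.uint8)[elig]  # (m, n_genes)
    member = patterns[:, gidx].astype(bool).T  # (len(genes), m)
    t = np.array([targets[g] for g in genes], dtype=float)

    # quick infeasibility screen: a positive target for a gene expressed in
    # no eligible state (or a sub-1 target for a gene expressed in all and
    # forced on) can never be met
    for gi, g in enumerate(genes):
        if not member[gi].any() and t[gi] > tol:
            raise FeasibilityError(
                f"target {t[gi]:.3f} for {g!r} but no eligible state expresses it"
            )
        if member[gi].all() and t[gi] < 1.0 - tol:
            raise FeasibilityError(
                f"target {t[gi]:.3f} for {g!r} but every eligible state expresses it"
            )

    for _ in range(max_tries):
        w = rng.dirichlet(np.ones(elig.size))
        for _ in range(max_ipf_iter):
            m = member @ w
            if np.all(np.abs(m - t) <= 0.5 * tol):
                break
            for gi in range(len(genes)):
                mg = member[gi] @ w
                on, off = member[gi], ~member[gi]
                if 0 < mg < 1:
                    w[on] *= t[gi] / mg
                    w[off] *= (1.0 - t[gi]) / (1.0 - mg)
                w = w / w.sum()
        m = member @ w
        if np.all(np.abs(m - t) <= tol):
            s = np.zeros(dtmc.n_states)
            s[elig] = w
            return s
    raise FeasibilityError(
        f"could not match marginals within {tol} after {max_tries} restarts"
    )
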