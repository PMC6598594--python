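"""Trajectory and model-vs-experiment comparison metrics.

Covers: log2 fold changes of marker prevalence, the concordance index
(fraction of markers whose modeled and measured fold changes share a
sign), Bland–Altman limits of agreement on the absolute differences,
the Jaccard–Needham distance between binary phenotype patterns and a
reference (prototypal mesenchymal) configuration, prevalence-weighted
distance trajectories, transformation efficiency, and detection of
phenotype couples differing at a single gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dtmc_builder import PhenotypeDTMC
from .dtmc_sim import PopulationTrajectory, simulate

__all__ = [
    "ReferenceState",
    "BlandAltmanResult",
    "jaccard_needham",
    "project_to_reference",
    "state_jnd",
    "weighted_jnd",
    "weighted_jnd_ensemble",
    "log2_fold_changes",
    "concordance_index",
    "bland_altman",
    "transformation_efficiency",
    "screen_high_efficiency",
    "find_single_gene_couples",
]


@dataclass(frozen=True)
class ReferenceState:
    """A reference expression pattern over a subset of the signature genes.

    Signature genes absent from the reference (e.g. the inducer) are masked
    out of distance computations.
    """

    genes: tuple[str, ...]
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.bits):
            raise ValueError("genes and bits must have equal length")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("reference bits must be 0/1")


def jaccard_needham(
    test: Sequence[int], ref: Sequence[int], mode: str = "standard"
) -> float:
    """Binary dissimilarity between two equal-length patterns, in [0, 1].

    ``standard`` (default): disagreements over the union of ones,
    ``(a01 + a10) / (a11 + a01 + a10)`` — 0 for identical patterns, 1 for
    disjoint supports; two all-zero patterns give 0.  ``literal`` follows
    the alternative verbal definition that counts shared zeros in the
    numerator, ``(TF + FT) / (TT + TF + FT)`` with TF = both 0 and FT =
    test 1 / reference 0 — kept for comparison although it is not a metric
    (d(x, x) > 0 whenever x has zero bits).
    """
    a = np.asarray(test, dtype=np.uint8)
    b = np.asarray(ref, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError(f"pattern length mismatch: {a.shape} vs {b.shape}")
    tt = int(np.count_nonzero((a == 1) & (b == 1)))
    ft = int(np.count_nonzero((a == 1) & (b == 0)))
    tf_disagree = int(np.count_nonzero((a == 0) & (b == 1)))
    if mode == "standard":
        den = tt + ft + tf_disagree
        return (ft + tf_disagree) / den if den else 0.0
    if mode == "literal":
        both_zero = int(np.count_nonzero((a == 0) & (b == 0)))
        den = tt + both_zero + ft
        return (both_zero + ft) / den if den else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def project_to_reference(
    pattern: Sequence[int], signature_genes: Sequence[str], ref: ReferenceState
) -> np.ndarray:
    """Restrict a signature pattern to the reference's gene set (in the
    reference's gene order)."""
    index = {g: i for i, g in enumerate(signature_genes)}
    missing = [g for g in ref.genes if g not in index]
    if missing:
        raise KeyError(f"reference genes absent from signature: {missing}")
    return np.array([pattern[index[g]] for g in ref.genes], dtype=np.uint8)


def state_jnd(
    patterns: Sequence[Sequence[int]],
    signature_genes: Sequence[str],
    ref: ReferenceState,
    mode: str = "standard",
) -> np.ndarray:
    """Per-state distance to the reference, with reference-gene masking."""
    ref_bits = np.asarray(ref.bits, dtype=np.uint8)
    return np.array(
        [
            jaccard_needham(project_to_reference(p, signature_genes, ref), ref_bits, mode)
            for p in patterns
        ]
    )


def weighted_jnd(
    traj: PopulationTrajectory,
    ref: ReferenceState,
    top_fraction: float = 1.0,
    mode: str = "standard",
) -> np.ndarray:
    """Prevalence-weighted distance to the reference, per iteration.

    With ``top_fraction < 1`` only the most prevalent states are averaged
    (e.g. 0.10 restricts to the 10% most expressed phenotypes), with their
    prevalences renormalized.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    d = state_jnd(traj.patterns, traj.signature_genes, ref, mode)
    n_states = traj.n_states
    k = max(1, math.ceil(top_fraction * n_states))
    out = np.empty(traj.prevalence.shape[0])
    for t, row in enumerate(traj.prevalence):
        if k == n_states:
            out[t] = float(row @ d)
        else:
            top = np.argsort(-row, kind="stable")[:k]
            w = row[top]
            total = w.sum()
            out[t] = float((w / total) @ d[top]) if total > 0 else 0.0
    return out


def weighted_jnd_ensemble(
    trajs: Sequence[PopulationTrajectory],
    ref: ReferenceState,
    top_fraction: float = 1.0,
    mode: str = "standard",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of the weighted distance across populations.

    Trajectories of different lengths are extended by holding their final
    (steady) vector.
    """
    series = [weighted_jnd(t, ref, top_fraction, mode) for t in trajs]
    T = max(len(s) for s in series)
    stack = np.array(
        [np.concatenate([s, np.full(T - len(s), s[-1])]) for s in series]
    )
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / math.sqrt(len(series))
        if len(series) > 1
        else np.zeros(T)
    )
    return mean, sem


def log2_fold_changes(
    traj: PopulationTrajectory, genes: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """log2 of the final/initial ratio of each marker's expressing fraction.

    Genes whose initial prevalence is zero are excluded (the ratio is
    undefined) and returned in the second element.
    """
    genes = list(traj.signature_genes) if genes is None else list(genes)
    rows = []
    excluded: list[str] = []
    for g in genes:
        start = traj.gene_prevalence(g, 0)
        end = traj.gene_prevalence(g, traj.prevalence.shape[0] - 1)
        if start <= 0:
            excluded.append(g)
            continue
        rows.append(
            {
                "gene_id": g,
                "initial": start,
                "final": end,
                "log2_fc": math.log2(end / start) if end > 0 else -math.inf,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "initial", "final", "log2_fc"]), excluded


def concordance_index(
    model_fc: Sequence[float], experimental_fc: Sequence[float]
) -> float:
    """Fraction of markers with the same fold-change sign in model and
    experiment (zero is concordant only with zero)."""
    m = np.asarray(model_fc, dtype=float)
    e = np.asarray(experimental_fc, dtype=float)
    if m.shape != e.shape or m.size == 0:
        raise ValueError("fold-change lists must be matched and nonempty")
    return float(np.mean(np.sign(m) == np.sign(e)))


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    outliers: list[int]
    diffs: np.ndarray = field(repr=False, default=None)
    means: np.ndarray = field(repr=False, default=None)


def bland_altman(
    model_fc: Sequence[float], experimental_fc: Sequence[float]
) -> BlandAltmanResult:
    """Limits of agreement on the absolute model-vs-experiment differences.

    bias = mean(|Δ|), LoA = bias ± 1.96·σ(|Δ|) (sample standard deviation);
    ``outliers`` indexes the pairs outside the limits.
    """
    m = np.asarray(model_fc, dtype=float)
    e = np.asarray(experimental_fc, dtype=float)
    if m.shape != e.shape or m.size < 2:
        raise ValueError("need at least two matched pairs")
    diffs = np.abs(m - e)
    means = (m + e) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = [int(i) for i in np.nonzero((diffs < loa_low) | (diffs > loa_high))[0]]
    return BlandAltmanResult(bias, loa_low, loa_high, outliers, diffs, means)


def transformation_efficiency(
    dtmc: PhenotypeDTMC,
    phenotype_id: int,
    ref: ReferenceState,
    max_steps: int = 1000,
    tol: float = 1e-9,
    top_fraction: float = 1.0,
    mode: str = "standard",
) -> float:
    """Drop in weighted distance to the reference when a population starts
    100% in one phenotype: weighted_jnd(first) − weighted_jnd(last)."""
    ids = [s.state_id for s in dtmc.states]
    if phenotype_id not in ids:
        raise KeyError(f"phenotype {phenotype_id} not in DTMC")
    s0 = np.zeros(dtmc.n_states)
    s0[ids.index(phenotype_id)] = 1.0
    traj = simulate(dtmc, s0, max_steps=max_steps, tol=tol)
    series = weighted_jnd(traj, ref, top_fraction, mode)
    return float(series[0] - series[-1])


def screen_high_efficiency(
    dtmc: PhenotypeDTMC,
    constraint: Mapping[str, int] | None,
    ref: ReferenceState,
    threshold: float = 0.40,
    max_steps: int = 1000,
    top_fraction: float = 1.0,
    mode: str = "standard",
) -> list[int]:
    """Phenotypes (satisfying the constraint) whose transformation
    efficiency exceeds the threshold (default 40%)."""
    if constraint:
        gidx = {g: dtmc.gene_index(g) for g in constraint}
        eligible = [
            s.state_id
            for s in dtmc.states
            if all(s.pattern[gidx[g]] == v for g, v in constraint.items())
        ]
    else:
        eligible = [s.state_id for s in dtmc.states]
    return [
        sid
        for sid in eligible
        if transformation_efficiency(
            dtmc, sid, ref, max_steps=max_steps, top_fraction=top_fraction, mode=mode
        )
        > threshold
    ]


def find_single_gene_couples(
    patterns: Mapping[object, Sequence[int]] | Sequence[tuple[object, Sequence[int]]],
    gene: int | str,
    genes: Sequence[str] | None = None,
) -> list[tuple[object, object]]:
    """Unordered phenotype pairs differing at exactly the given gene.

    ``patterns`` maps phenotype id -> bit pattern (all aligned to the same
    gene order); ``gene`` is a position or, with ``genes`` provided, a gene
    name.  Pairs are returned sorted, smaller id first.
    """
    if isinstance(gene, str):
        if genes is None:
            raise ValueError("gene given by name requires the gene-order list")
        gene = list(genes).index(gene)
    items = list(patterns.items()) if isinstance(patterns, Mapping) else list(patterns)
    arrs = [(pid, np.asarray(p, dtype=np.uint8)) for pid, p in items]
    couples = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            pid_a, a = arrs[i]
            pid_b, b = arrs[j]
            diff = np.nonzero(a != b)[0]
            if diff.size == 1 and diff[0] == gene:
                try:
                    pair = tuple(sorted((pid_a, pid_b)))
                except TypeError:
                    pair = tuple(sorted((pid_a, pid_b), key=str))
                couples.append(pair)
    try:
        return sorted(couples)
    except TypeError:
        return sorted(couples, key=lambda c: tuple(map(str, c)))
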