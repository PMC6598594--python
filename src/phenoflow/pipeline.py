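"""End-to-end orchestration: network → scores → attractors → DTMC → simulation → report.

A :class:`RunConfig` drives six resumable stages; every artifact is a pure
function of (inputs, config, seeds).  Per-stage seeds are derived from the
master seed and the stage name, so a stage can be regenerated in isolation
and reruns are byte-identical.  Timings and convergence summaries go to
the logger, never into artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, bn_dynamics, dtmc_builder, dtmc_sim, pathway_io, topology
from .analysis import ReferenceState
from .network import BooleanNetwork

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "derive_seed", "STAGES"]

STAGES = ["network", "scores", "attractors", "dtmc", "simulate", "analyze"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (serialized into the run directory)."""

    kgml_dir: str
    out_dir: str
    expr_path: str | None = None
    master_seed: int = 0
    # pathway selection
    min_markers: int | None = None
    marker_list: list[str] = field(default_factory=list)
    # scoring
    score_threshold: float = -2.5
    log_base: str = "e"  # "e" | "10"
    inducer: str | None = None
    undirected_eccentricity: bool = False
    # attractor search
    attractor_n_sims: int = 2000
    p_grid: list[float] = field(default_factory=lambda: list(bn_dynamics.DEFAULT_P_GRID))
    max_iter: int = 1000
    # transition campaign
    transition_n_sims: int = 2000
    flip_start: float = 0.05
    flip_step: float = 0.05
    # population simulation
    n_populations: int = 20
    require_gene: str | None = None
    marginal_tol: float = 0.05
    steady_tol: float = 1e-9
    max_steps: int = 500
    # analysis
    reference_genes: list[str] = field(default_factory=list)
    reference_bits: list[int] = field(default_factory=list)
    couple_gene: str | None = None
    derive_reference: bool = False
    top_fraction: float = 1.0
    jnd_mode: str = "standard"
    efficiency_threshold: float = 0.40

    def __post_init__(self) -> None:
        # YAML 1.1 reads bare scientific notation like 1e-9 as a string
        for name in ("score_threshold", "flip_start", "flip_step", "marginal_tol",
                     "steady_tol", "top_fraction", "efficiency_threshold"):
            setattr(self, name, float(getattr(self, name)))
        self.p_grid = [float(p) for p in self.p_grid]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )

    def log_base_value(self) -> float:
        return 10.0 if str(self.log_base) == "10" else float(np.e)

    def reference(self) -> ReferenceState | None:
        if not self.reference_genes:
            return None
        return ReferenceState(tuple(self.reference_genes), tuple(self.reference_bits))


@dataclass
class RunResult:
    run_dir: Path
    executed: list[str]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage_network(cfg: RunConfig, run_dir: Path) -> None:
    kgml_files = sorted(Path(cfg.kgml_dir).glob("*.xml"))
    if not kgml_files:
        raise FileNotFoundError(f"no KGML files in {cfg.kgml_dir}")
    pathways = [pathway_io.parse_kgml(f) for f in kgml_files]
    if cfg.min_markers is not None:
        pathways = pathway_io.filter_pathways(pathways, cfg.marker_list, cfg.min_markers)
        if not pathways:
            raise ValueError("no pathway passed the marker filter")
    nets = [pathway_io.pathway_to_boolean(p) for p in pathways]
    merged = pathway_io.merge_networks(nets)
    major = pathway_io.largest_component(merged)
    logger.info(
        "network: %d pathways -> merged %d nodes / %d edges; major component %d nodes",
        len(pathways), merged.n_nodes, merged.n_edges, major.n_nodes,
    )
    major.to_json(run_dir / "net.json")


def _load_net(run_dir: Path) -> BooleanNetwork:
    return BooleanNetwork.from_json(run_dir / "net.json")


def _stage_scores(cfg: RunConfig, run_dir: Path) -> None:
    net = _load_net(run_dir)
    scores = topology.score_nodes(
        net, log_base=cfg.log_base_value(), undirected=cfg.undirected_eccentricity
    )
    sig = topology.select_signature(scores, cfg.score_threshold, cfg.inducer)
    scores = scores.copy()
    scores["in_signature"] = [n in sig.genes for n in scores.index]
    scores.index.name = "node"
    scores.to_csv(run_dir / "scores.tsv", sep="\t", float_format="%.10g")
    _write_json(
        run_dir / "signature.json",
        {
            "genes": sig.genes,
            "threshold": sig.threshold,
            "inducer": sig.inducer,
            "added_not_scored": sig.added_not_scored,
        },
    )
    logger.info("scores: signature of %d markers at threshold %s", len(sig), cfg.score_threshold)


def _load_signature(run_dir: Path) -> list[str]:
    return json.loads((run_dir / "signature.json").read_text())["genes"]


def _stage_attractors(cfg: RunConfig, run_dir: Path) -> None:
    net = _load_net(run_dir)
    rng = np.random.default_rng(derive_seed(cfg.master_seed, "attractors"))
    res = bn_dynamics.attractor_campaign(
        net, cfg.attractor_n_sims, tuple(cfg.p_grid), cfg.max_iter, rng
    )
    logger.info(
        "attractors: %d/%d converged, %d distinct fixed points",
        res.n_converged, res.n_sims, len(res.attractors),
    )
    _write_json(
        run_dir / "attractors.json",
        {
            "node_order": res.node_order,
            "attractors": [
                {"bits": bn_dynamics.state_to_bits(s), "count": c}
                for s, c in res.attractors
            ],
            "n_sims": res.n_sims,
            "n_converged": res.n_converged,
        },
    )


def _stage_dtmc(cfg: RunConfig, run_dir: Path) -> None:
    net = _load_net(run_dir)
    data = json.loads((run_dir / "attractors.json").read_text())
    attractors = [
        (bn_dynamics.bits_to_state(a["bits"]), a["count"]) for a in data["attractors"]
    ]
    sig_genes = _load_signature(run_dir)
    states = dtmc_builder.merge_attractors(attractors, sig_genes, net)
    rng = np.random.default_rng(derive_seed(cfg.master_seed, "dtmc"))
    records = dtmc_builder.transition_campaign(
        net, states, sig_genes, cfg.transition_n_sims,
        cfg.flip_start, cfg.flip_step, cfg.max_iter, rng,
    )
    dtmc = dtmc_builder.build_matrix(records, states, sig_genes)
    logger.info(
        "dtmc: %d phenotype states from %d attractors; snap fraction %.3f",
        dtmc.n_states, len(attractors), dtmc.build_log.get("snap_fraction", 0.0),
    )
    _write_json(run_dir / "dtmc.json", dtmc_builder.dtmc_to_dict(dtmc))


def _load_dtmc(run_dir: Path):
    return dtmc_builder.dtmc_from_dict(json.loads((run_dir / "dtmc.json").read_text()))


def _stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    dtmc = _load_dtmc(run_dir)
    rng = np.random.default_rng(derive_seed(cfg.master_seed, "simulate"))
    if cfg.expr_path is None:
        raise ValueError("simulate stage requires expr_path")
    expr = dtmc_sim.read_expression_table(cfg.expr_path)
    constraint = {cfg.require_gene: 1} if cfg.require_gene else None
    # markers without expression data carry no marginal constraint, and a
    # marker that is constant across eligible states cannot be tuned
    measured = set(expr["gene_id"])
    patterns = np.array(dtmc.patterns(), dtype=np.uint8)
    if constraint:
        gi = dtmc.gene_index(cfg.require_gene)
        patterns = patterns[patterns[:, gi] == 1]
    target_genes = []
    for g in dtmc.signature_genes:
        if g == cfg.require_gene or g not in measured:
            continue
        col = patterns[:, dtmc.gene_index(g)]
        if col.min() != col.max():
            target_genes.append(g)
    skipped = [g for g in dtmc.signature_genes if g not in target_genes and g != cfg.require_gene]
    if skipped:
        logger.info("simulate: markers without tunable marginal: %s", skipped)
    trajectories = []
    n_rejected = 0
    for _ in range(cfg.n_populations):
        # iterative search for a coherent population: target draws that
        # cannot be matched on the eligible states are discarded and redrawn
        for _attempt in range(20):
            targets = dtmc_sim.marker_prevalence_targets(expr, target_genes, rng)
            try:
                s0 = dtmc_sim.sample_virtual_population(
                    dtmc, targets, constraint, tol=cfg.marginal_tol,
                    max_tries=10, rng=rng,
                )
                break
            except dtmc_sim.FeasibilityError:
                n_rejected += 1
        else:
            raise dtmc_sim.FeasibilityError(
                "no coherent virtual population found in 20 target draws"
            )
        trajectories.append(
            dtmc_sim.simulate(dtmc, s0, max_steps=cfg.max_steps, tol=cfg.steady_tol)
        )
    if n_rejected:
        logger.info("simulate: %d incoherent target draws rejected", n_rejected)
    T = max(t.prevalence.shape[0] for t in trajectories)
    padded = np.array(
        [
            np.vstack([t.prevalence] + [t.prevalence[-1:]] * (T - t.prevalence.shape[0]))
            for t in trajectories
        ]
    )
    mean_prev = padded.mean(axis=0)
    logger.info(
        "simulate: %d populations, mean trajectory length %d", len(trajectories), T
    )
    _write_json(
        run_dir / "traj.json",
        {
            "signature_genes": dtmc.signature_genes,
            "patterns": [bn_dynamics.state_to_bits(p) for p in dtmc.patterns()],
            "mean_prevalence": mean_prev.tolist(),
            "per_population_prevalence": padded.tolist(),
            "n_populations": cfg.n_populations,
        },
    )


def _stage_analyze(cfg: RunConfig, run_dir: Path) -> None:
    dtmc = _load_dtmc(run_dir)
    data = json.loads((run_dir / "traj.json").read_text())
    report = run_dir / "report"
    report.mkdir(exist_ok=True)
    patterns = [tuple(int(c) for c in p) for p in data["patterns"]]
    mean_traj = dtmc_sim.PopulationTrajectory(
        prevalence=np.array(data["mean_prevalence"]),
        signature_genes=data["signature_genes"],
        patterns=patterns,
    )
    fc, excluded = analysis.log2_fold_changes(mean_traj)
    fc.to_csv(report / "fold_changes.tsv", sep="\t", index=False, float_format="%.10g")
    if excluded:
        logger.info("analyze: genes excluded from fold change (zero start): %s", excluded)
    ref = cfg.reference()
    if ref is None and cfg.derive_reference:
        # default reference: the pattern of the most prevalent final state,
        # restricted to the non-inducer markers
        final = mean_traj.prevalence[-1]
        top = int(np.argmax(final))
        genes = [g for g in mean_traj.signature_genes if g != cfg.require_gene]
        gidx = [mean_traj.signature_genes.index(g) for g in genes]
        ref = ReferenceState(
            tuple(genes), tuple(int(patterns[top][i]) for i in gidx)
        )
        logger.info("analyze: derived reference %s over %s", ref.bits, ref.genes)
    if ref is not None:
        per_pop = [
            dtmc_sim.PopulationTrajectory(
                prevalence=np.array(p),
                signature_genes=data["signature_genes"],
                patterns=patterns,
            )
            for p in data["per_population_prevalence"]
        ]
        mean, sem = analysis.weighted_jnd_ensemble(
            per_pop, ref, cfg.top_fraction, cfg.jnd_mode
        )
        pd.DataFrame(
            {"iteration": np.arange(mean.size), "weighted_jnd": mean, "sem": sem}
        ).to_csv(report / "weighted_jnd.tsv", sep="\t", index=False, float_format="%.10g")
        constraint = {cfg.require_gene: 1} if cfg.require_gene else None
        rows = []
        for s in dtmc.states:
            if constraint and any(
                s.pattern[dtmc.gene_index(g)] != v for g, v in constraint.items()
            ):
                continue
            eff = analysis.transformation_efficiency(
                dtmc, s.state_id, ref, max_steps=cfg.max_steps,
                top_fraction=cfg.top_fraction, mode=cfg.jnd_mode,
            )
            rows.append(
                {
                    "state_id": s.state_id,
                    "pattern": bn_dynamics.state_to_bits(s.pattern),
                    "efficiency": eff,
                    "high": eff > cfg.efficiency_threshold,
                }
            )
        pd.DataFrame(rows, columns=["state_id", "pattern", "efficiency", "high"]).to_csv(
            report / "efficiency.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if cfg.couple_gene and cfg.couple_gene in dtmc.signature_genes:
        couples = analysis.find_single_gene_couples(
            {s.state_id: s.pattern for s in dtmc.states},
            cfg.couple_gene,
            dtmc.signature_genes,
        )
        pd.DataFrame(couples, columns=["phenotype_a", "phenotype_b"]).to_csv(
            report / "couples.tsv", sep="\t", index=False
        )


_STAGE_FUNCS = {
    "network": (_stage_network, ["net.json"]),
    "scores": (_stage_scores, ["scores.tsv", "signature.json"]),
    "attractors": (_stage_attractors, ["attractors.json"]),
    "dtmc": (_stage_dtmc, ["dtmc.json"]),
    "simulate": (_stage_simulate, ["traj.json"]),
    "analyze": (_stage_analyze, ["report/fold_changes.tsv"]),
}


def make_demo_workspace(workdir: str | Path, master_seed: int = 0) -> RunConfig:
    """Write a self-contained demo input set (toy KGML pathways, a synthetic
    expression table) plus a small-scale config, and return the config.

    The demo runs the whole method end-to-end at desk scale: three
    overlapping toy pathways, a clamped input-free inducer, a few thousand
    simulations.
    """
    from .synthetic import synthetic_expression_table, toy_kgml

    workdir = Path(workdir)
    kgml_dir = workdir / "kgml"
    kgml_dir.mkdir(parents=True, exist_ok=True)
    for i in range(3):
        (kgml_dir / f"pathway{i}.xml").write_text(
            toy_kgml(f"synthetic{i:02d}", offset=2 * i)
        )
    genes = [f"syn:G{i}" for i in range(1, 13)]
    expr = synthetic_expression_table(genes, "graded", seed=master_seed)
    expr_path = workdir / "expr.tsv"
    expr.to_csv(expr_path, sep="\t", index=False)
    return RunConfig(
        kgml_dir=str(kgml_dir),
        out_dir=str(workdir / "run"),
        expr_path=str(expr_path),
        master_seed=master_seed,
        score_threshold=-2.5,
        inducer="syn:G1",
        require_gene="syn:G1",
        attractor_n_sims=2000,
        transition_n_sims=1000,
        max_iter=200,
        n_populations=10,
        max_steps=200,
        couple_gene="syn:G1",
        derive_reference=True,
    )


def run_pipeline(cfg: RunConfig, resume: bool = True) -> RunResult:
    """Execute all stages; with ``resume`` skip stages whose artifacts exist.

    Failure in a stage raises with the stage name; earlier artifacts are
    preserved.
    """
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_file(run_dir / "config.json")
    executed: list[str] = []
    for stage in STAGES:
        func, artifacts = _STAGE_FUNCS[stage]
        if resume and all((run_dir / a).exists() for a in artifacts):
            logger.info("stage %s: artifacts present, skipped", stage)
            continue
        t0 = time.perf_counter()
        try:
            func(cfg, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
        executed.append(stage)
    return RunResult(run_dir, executed)
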