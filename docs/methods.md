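# Methods

## Model overview

`phenoflow` couples two formalisms. A **signed Boolean network** gives a
parameter-free single-cell model of a signal-transduction map: each gene
or complex holds a binary value, and edges carry activation (+1) or
inhibition (−1). A **discrete-time Markov chain over phenotypes** gives
the population model: its states are equivalence classes of Boolean
attractors (grouped by the expression pattern of a small gene signature)
and its transition probabilities are estimated by perturbation
simulations of the Boolean tier.

The only inputs are curated pathway files (KGML) and, optionally, a bulk
expression summary (gene → baseMean) used to initialize populations. No
kinetic rates are fitted anywhere.

## Boolean tier

**Conversion.** Fixed mapping from KGML relation subtypes:
activation/expression → +1 edge into a MAJ node; inhibition → −1 edge
into a MAJ node; binding/association, complex and dissociation → an AND
node representing the complex, identified by the sorted tuple of member
gene identifiers (so the same complex unifies across pathways) and fed by
+1 edges from the members; "missing interaction" and "remove" are
skipped. Unrecognized subtypes are counted and skipped, never silently
dropped. Regulation that *targets* a complex entry is redistributed onto
the complex's members, preserving the invariant that AND nodes receive
only activating inputs. When merging gives the same identifier both
rules, AND wins: requiring all parts present is the stricter physical
constraint. Node identity is exact string match on the stable identifier
(Entrez-style ids in real data); no symbol aliasing is attempted.

**Update scheme.** One iteration (*sweep*) draws a fresh uniform random
permutation of the nodes and updates them sequentially against the
latest values — asynchronous in flavor, but every node is revised exactly
once per iteration. Rules:

* AND: ON iff all inputs ON;
* MAJ: Δ = (active activators) − (active inhibitors); Δ>0 → ON, Δ<0 →
  OFF, Δ=0 → hold. Only *active* inputs count: an OFF inhibitor exerts
  no repression.

The tie-hold choice (a `tie→0` mode is also provided) avoids spurious
oscillation and makes input-free nodes constants, which is exactly what
lets an external inducer such as TGF-β1 be clamped ON. Because a fixed
point requires every node to reproduce its own value, the set of
single-state attractors is independent of the update order; this is
asserted on every converged simulation and checked against exhaustive
2^n enumeration in the tests.

**Attractor search.** Simulations start from random configurations with
activation probability swept over a 21-point grid (0–100% in 5% steps,
runs split evenly, remainder to 50%) and stop when a sweep leaves the
state unchanged or after `max_iter` sweeps (default 10^5, the reference
stopping criterion). Converged end states are deduplicated exactly
(states are binary) with occurrence counts as empirical basin sizes.
Cyclic attractors are deliberately not detected or reported —
non-converged runs are only counted — because the phenotype
interpretation rests on length-1 attractors.

## Signature extraction

Out-degree and eccentricity both increase with regulatory influence but
span different ranges, so each is converted to a rank (1 = largest; ties
get the mean of tied positions, which removes iteration-order
nondeterminism) and combined as `S = −log(R_OD + R_E)`. Natural log is
the default; the base only rescales the threshold and is configurable
(base 10 available). Eccentricity uses *directed* paths out of the node
(downstream influence); sinks get E = 0 and rank last. An undirected
variant is available behind a flag. Complex nodes are scored exactly
like gene nodes. The signature is every node with `S ≥ threshold`
(default −2.5), optionally completed by an inducer node appended without
being scored.

## DTMC construction

Attractors merge by exact signature pattern; each phenotype keeps its
representative full states and the summed basin counts, and state ids
are assigned in descending basin weight. The transition campaign
distributes runs evenly over source phenotypes; each run perturbs a
uniformly chosen representative (flip probability starting at 5%,
escalating by 5% whenever the run returns to the source phenotype or
fails to converge, up to 100%, at which point the run is recorded as a
failure). End states whose pattern is unknown are snapped to the nearest
known phenotype by signature Hamming distance (ties: larger basin, then
smaller id); the snap fraction is reported in the build log, not
asserted.

Probabilities follow the corrected frequency estimate: `raw_ij =
(N_ij/N_i) · 1/(d_ij · I_ij)`, favoring transitions between similar
phenotypes and shorter simulations. Rows are then **renormalized to sum
to one** — the only reading under which the population iteration
conserves mass. Distances are computed on signature patterns (the
chain's own state space); sources with no recorded exit become explicit,
logged absorbing states.

## Population tier

`P` is stored row-stochastic (row = source) and applied as `s(t+1) =
Pᵀ s(t)`, which moves mass along recorded source→destination edges and
keeps Σs = 1 (renormalized within 1e−12 against float drift).
Simulation stops when the sup-norm change drops below `tol` (default
1e−9) or at `max_steps`.

**Virtual populations.** Marker targets follow the baseMean-ratio rule:
the most expressed gene gets a random prevalence p* ~ U(0.5, 1), every
other gene p*·(baseMean ratio). The fitting procedure is randomized
Dirichlet initialization over the eligible states (e.g. inducer-ON)
followed by multiplicative marginal fitting (IPF-style), accepting a
vector when every marginal is within `tol = 0.05` of target and
restarting otherwise; infeasible targets fail explicitly. The pipeline
layer additionally redraws the target vector when a draw proves
infeasible — the published procedure is stated only as an iterative
search for expression-coherent populations, so the concrete algorithm
here is this package's design choice. Markers without expression data
or constant across eligible states carry no marginal constraint (the
same convention under which FOXO6, unquantified in the reference
dataset, was excluded from validation).

## Analysis metrics

* **Jaccard–Needham distance**: default is the standard binary Jaccard
  dissimilarity, disagreements over the union of ones. The alternative
  verbal formulation that counts shared zeros in the numerator is
  implemented as `mode="literal"` for comparison, but it is not a metric
  (d(x,x) > 0 for patterns with zeros) and contradicts the expected
  behavior of a distance that shrinks as a population approaches the
  reference, so it is not the default. Reference patterns may cover only
  a subset of signature genes; the rest are masked.
* **Weighted trajectories**: per iteration, the prevalence-weighted mean
  distance to the reference, optionally restricted to the top fraction
  of most prevalent phenotypes (0.10 mirrors the reported convention)
  with renormalized weights; ensembles report mean ± standard error.
* **Fold changes**: log2 of final vs initial expressing fraction per
  marker, computed on prevalences (scale-invariant, so absolute cell
  counts only set units); zero-initial markers are excluded with a note.
* **Concordance**: fraction of markers with matching fold-change sign
  (zero matches only zero). **Bland–Altman**: bias = mean absolute
  difference, limits of agreement bias ± 1.96·σ with the sample standard
  deviation (ddof = 1).
* **Transformation efficiency**: start 100% in one phenotype, simulate
  to steady state, report first-minus-last weighted distance; the
  screen keeps phenotypes above 0.40.
* **Couples**: unordered pattern pairs differing at exactly one given
  gene, by exhaustive pairwise scan.

## Synthetic fixtures

The generators emulate the *structure* of the real inputs, not their
biology: toy KGML documents exercise every interaction subtype;
Erdős–Rényi signed networks (with optional complexes and hubs wired to
≥10× the median out-degree) provide scoring and dynamics substrates; the
planted-attractor construction uses complete-digraph 3-node positive
loops joined by a ring of single inter-loop inhibitions, chosen so the
fixed points are provably exactly the 2^k loop ON/OFF combinations under
tie-hold (a simple cycle would admit extra mixed fixed points);
expression tables come in graded/uniform/sparse/random profiles. Passing
tests on these fixtures demonstrates the machinery — conversion,
dynamics, estimation, metrics — under controlled truth; they say nothing
about the biological fidelity of any particular KEGG snapshot, and the
published full-scale network statistics (hundreds of nodes and DTMC
states) depend on historical database content that is out of scope here.

## Problem sizes and defaults

Full-scale defaults follow the reference analysis: 4·10^5 simulations
for attractor search plus 4·10^5 for transitions, `max_iter` 10^5,
5%-step activation grid and flip escalation, score threshold −2.5, 1000
virtual populations (2000 reported in places; the count is a flag). The
bundled demo and test configurations scale these to desk size (toy
pathways of ~20 nodes, 2·10^3 attractor and 10^3 transition simulations,
10–20 populations, `max_iter` 200) — chosen as the package's own
illustration sizes; all are configurable.

## Numerical choices and degenerate inputs

Row-stochasticity is enforced to 1e−12. Exact state equality (no
tolerance) deduplicates attractors. Ties are broken deterministically
throughout (mean ranks; component ordering by size then lexicographic
node set; snapping by distance, basin, id). Empty networks, empty
attractor lists, infeasible targets and dimension mismatches raise
typed errors. Per-stage seeds derive from SHA-256 of (master seed, stage
name), keeping every stage independently reproducible and below 2^31.

## Known limitations

* Only fixed-point attractors are modeled; limit cycles are counted as
  non-converged and discarded.
* The Boolean abstraction collapses dose, time and post-translational
  regulation; agreement with mRNA data is expected to be directional,
  not quantitative.
* Transition probabilities inherit sampling noise from the perturbation
  campaign; no uncertainty quantification is attached.
* The population model is a deterministic prevalence iteration, not a
  stochastic single-cell simulation.
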