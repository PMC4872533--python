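# Methods

This note documents the models and conventions implemented in `pnc`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Network assembly

Interaction evidence comes in three kinds: plain physical interactions
(`ppi`, undirected), kinase/phosphatase–substrate interactions (`kpi`,
directed by nature) and gene-knockout ordered pairs (`ko`, directed, each
carrying a p-value). Knockout pairs are retained only when *p* < 0.001;
the boundary is exclusive (a pair at exactly 0.001 is removed). Assembly
rules are applied to the *multiset* of records, so the result is
independent of record order:

- self loops are dropped (the node is kept in the node set);
- duplicate records between a pair collapse to one edge;
- if a pair has both directed and undirected evidence, only the directed
  edge is kept (a `ppi` record never overrides `kpi`/`ko` direction);
- a pair supported in both opposite directions becomes a single
  undirected edge.

Node identifiers are opaque, case-sensitive strings; no identifier
normalisation or ortholog mapping is attempted — inputs are assumed
pre-unified. Isolated nodes survive I/O: the TSV dialect has explicit
`!node` lines, SIF writes bare node lines, GraphML keeps them natively.

## Orientation

Given a mixed graph and source–target constraints, an orientation picks
one direction per undirected edge. A constraint is *satisfied* when the
oriented network contains a directed source→target path whose length
equals the source–target shortest-path length in the original graph with
directions ignored (the strong criterion). A `criterion="reachable"`
relaxation accepts any directed path; the strong rule is the default
because path-length-preserving orientation is the stricter, better-posed
reading, and both belong to the same algorithm family.

- **Exact mode** enumerates all `2^U` orientation vectors (edges sorted
  lexicographically; bit 0 orients an edge from its smaller to its larger
  endpoint). Ties are broken by the lexicographically smallest vector.
  The contract is the optimum, not the solver; enumeration is limited to
  `max_undirected = 20` edges by default.
- **Greedy mode** processes constraints by increasing direction-blind
  path length (short constraints are cheapest to satisfy and conflict
  least). For each unsatisfied constraint it searches a shortest path
  through pre-directed, already-fixed-consistent and still-free edges,
  fixing free edges along the found path; leftover free edges are
  oriented from the lower- to the higher-total-degree endpoint (ties
  lexicographic). The heuristic is deterministic; its satisfied count
  never exceeds the exact optimum (asserted against enumeration in the
  tests).

KPI records enter as pre-directed edges. Each ko pair contributes both a
directed candidate edge and a path constraint; when a ko direction
contradicts a KPI edge, the KPI direction wins and the conflict is
logged.

The agreement between two independently oriented networks is the fraction
of node pairs adjacent in both whose orientation coincides.

## Structural controllability

For x′ = Ax + Bu with A carrying a weight per directed edge j→i, the
minimum number of driver nodes is `N_D = max(N − |M*|, 1)` with `M*` a
maximum matching of the bipartite lift (out-copies left, in-copies right,
one bipartite edge per arc). Drivers are the nodes whose in-copy is
unmatched; with a perfect matching the floor of one input applies and the
lexicographically smallest node is designated. The floor is required so a
directed cycle needs one driver — at least one external signal always
exists.

Matching is computed with Kuhn's augmenting-path algorithm over
deterministic (sorted) adjacency. Node classification removes each node
with its incident edges (the remainder may be disconnected — allowed),
recomputes `N'_D` on the remaining N−1 nodes with the same floor
convention, and labels the node critical/redundant/ordinary by the sign
of `N'_D − N_D`.

*Incremental reclassification.* Deleting a node invalidates at most two
matched edges of the baseline maximum matching, so each per-node
recomputation warm-starts from the baseline and sweeps augmenting
searches over exposed out-copies (with the shared-visited Hungarian-forest
optimisation, reset after every success) until none succeeds; by Berge's
lemma the result is a maximum matching of the reduced graph. The fast
path is asserted equal to full recomputation on exhaustive 3-node and
randomized small digraphs. Note that a single augmenting path can consume
both newly exposed copies at once, after which a further augmenting path
between previously exposed vertices may exist — hence the sweep runs to
exhaustion rather than only from the freed copies.

*Kalman cross-check.* A numeric realisation draws independent
uniform(0.2, 1.0) weights for every edge and driver input (structural
controllability is a generic property; any fixed weights are a
measure-zero risk) and checks `rank [B, AB, …, A^{N−1}B] = N` via singular
values with tolerance `max(dims) · eps · σ_max`. B has one one-hot column
per driver. Accessibility is part of structural controllability: when a
source strongly-connected component is unreachable from every driver (an
inaccessible cycle), the first input column gets an extra nonzero entry on
one node of that component — the input count stays `N_D`, matching the
minimum-inputs theorem.

*Robustness.* `invert_random_edges` reverses `⌊f·|E|⌋` distinct uniformly
chosen edges; a reversal that would duplicate an existing edge merges with
it (the graph stays simple) and is logged. The curve classifies `reps`
independent inversions per fraction (0 to 20% by default) and reports the
mean critical-set difference, `100·|A△B|/|A∪B|` (0 when both sets are
empty).

## Distances and knockdown

Two "diameter" readings coexist and both are implemented:

- `mean_geodesic` — the characteristic path length: the average shortest
  path over ordered (directed mode) or unordered (undirected mode) pairs,
  with unreachable pairs excluded from numerator and denominator.
  Directed PPI networks invariably contain unreachable ordered pairs, so
  exclusion keeps the quantity finite; `direction_mode="as_undirected"`
  reproduces the alternative reading. This is the knockdown metric.
- `standard_diameter` — the maximum (finite) node eccentricity; per-node
  eccentricity over out-distances is undefined for nodes reaching nothing
  and is reported as missing.

Progressive knockdown of a target node removes random subsets of its
removal pool — its incident edges (default: a protein knockdown removes
its interactions) or its first neighbours (`mode="neighbor_nodes"`) —
at fractions 0, step, …, 1, with `reps` replicates per fraction,
recomputing the mean geodesic each time. Subsets at successive fractions
are independent by default (each fraction is a fresh random partial
knockdown); `nested=True` grows them monotonically. Endpoints are exact
by construction: fraction 0 is the intact network, fraction 1 equals
one-shot deletion of the whole pool. Everything is seeded through a
`SeedSequence` tree, so curves are bit-reproducible.

Distance computations run on igraph's C core; on a 2,000-node network a
101-step, 3-replicate curve takes seconds.

## Enrichment statistics

- Binary attributes (≥ 1 PTM site of a type, miRNA target,
  phospho-binding domain, complex membership) are tested critical vs
  non-critical with the two-sided Fisher exact test (p = sum of
  hypergeometric probabilities of tables no more probable than the
  observed one); the reported effect is the sample odds ratio ad/bc,
  infinite on a zero denominator. PTM "regulation" is binarised per node
  as ≥ 1 annotated site; site counts are retained for sensitivity
  re-analysis.
- Numeric attributes (total degree k = k_in + k_out, disorder fraction,
  degradation rate) are compared across the three classes with
  Kruskal–Wallis; two-group comparisons use the Wilcoxon rank-sum, exact
  (subset-count dynamic programming over the permutation null, two-sided
  p = doubled smaller tail capped at 1) for untied samples up to 12 per
  group, tie-corrected normal approximation otherwise.
- Raw p-values are always reported; Benjamini–Hochberg adjustment across
  the attribute family is on by default and can be disabled
  (`adjust=False`) for parity with raw-p-only reporting.
- The critical:redundant PTM ratio is the fraction of critical nodes
  carrying the PTM divided by the same fraction among redundant nodes.
- Interface rates use a whole-network normalisation: class-incident
  edges of an interface type divided by total interactions, divided by
  total nodes in the network (a per-class denominator is available).
- Hubs are nodes with total degree at or above the 90th percentile of the
  degree multiset; ties at the threshold are included.
- Degree distributions are fitted by discrete maximum likelihood,
  `P(k) ∝ k^(−γ)` for k ≥ xmin, with the Hurwitz-zeta normalised
  log-likelihood maximised numerically; `xmin="auto"` minimises the
  Kolmogorov–Smirnov distance between empirical and fitted tails. Fits
  require ≥ 50 tail observations and a non-degenerate tail.

## Synthetic data: what it emulates, and what it does not

`scale_free_directed` is a directed configuration model: total degrees
are drawn from a truncated zeta law on k_min…k_max (k_max ≈ √n, the usual
structural cutoff), split binomially into in/out stubs, balanced by
moving single stubs between the two sides, and matched uniformly; self
loops and parallel edges are rewired for a bounded number of rounds and
leftover collisions are dropped (erased configuration model, logged).
This gives direct control of the degree exponent γ that the analysis
asserts for real phospho-PPI networks. Defaults: γ = 3 and k_min = 1
(the asserted `P(k) = A·k^(−3)` from k = 1). Simulation fixtures that
need a well-connected giant component (knockdown and robustness curves)
use k_min = 2; that choice is about connectivity, not about the tail.

`plant_attributes` classifies first, then annotates: attribute
probabilities are conditional on the node's own computed class, mirroring
the observational direction of the real analysis without claiming
causality. Critical nodes receive each binary attribute with probability
q where odds(q) = OR · odds(p); others receive the base rate p. Default
planted odds ratios echo the reported qualitative magnitudes — 2 for
phosphorylation, acetylation, ubiquitination and miRNA targeting, 6 for
sumoylation (the one effect size stated quantitatively, ">6 times"), 3
for phospho-binding domains and complex membership, and a 2-fold DLI bias
on critical-incident edges; base rates (0.6 phosphorylation, 0.15
acetylation, 0.2 ubiquitination, 0.02 sumoylation, 0.3 miRNA, 0.1 domain,
0.1 complex, 0.4 DLI) are plausible round figures for a phosphoprotein
network, chosen once. Disorder fractions (Beta(2,5)) and degradation
rates (lognormal) are drawn class-independently — the real analysis found
no class difference in either. The seven highest-degree nodes share a
"paralog family" label so knockdown simulations have 14-3-3-like targets.

What the generator does *not* emulate: degree–degree correlations,
community/modular structure, the coupling between interface type and
interface structure, duplication–divergence growth, and annotation noise
or missingness. Passing tests therefore demonstrate that the pipeline
recovers what was planted under an idealised independence model — not
that real networks satisfy these assumptions.

`make_orientation_instance` generates a reciprocal-free ground-truth
digraph (reverse duplicates are treated as collisions), strips direction
from a random fraction of edges, and samples constraints from the truth's
reachable ordered pairs, so orientation output can be scored against the
truth by directed-edge agreement.

## Problem sizes and determinism

The validation suite runs at sizes chosen to make each check sharp but
cheap: exhaustive 3-node digraphs plus 500 random ≤ 7-node digraphs
against a bitmask-DP matching oracle; 100 random mixed graphs with ≤ 12
undirected edges against exhaustive orientation enumeration; exponent
recovery at n = 10⁴; null calibration with 200 simulated annotation draws
on a fixed 1,300-node class assignment; 50 end-to-end planted-effect runs
at n = 600 (a single deeper run at n = 1,500); knockdown endpoint checks
at n = 2,000; robustness reproducibility at n = 200.

Every stochastic component takes an explicit seed; the CLI derives
per-stage seeds from one global seed via a fixed `SeedSequence` splitting
scheme, so stages can be rerun in isolation and full reruns are
byte-identical. Output artifacts carry the tool version, seed and a
config hash in their headers.

## Known limitations

- Exact orientation is exponential in the number of undirected edges and
  is intended for validation and small subproblems; the greedy heuristic
  carries no optimality guarantee beyond never exceeding the optimum.
- The minimum-driver analysis is purely structural (matching-based); it says
  nothing about control energy or about weighted/nonlinear dynamics.
- Classification treats one node removal at a time; combinatorial
  removals are out of scope.
- Fisher tests on sparse attributes (e.g. a 2% base rate in small
  classes) are conservative, which slightly depresses the family's
  aggregate type-I rate.
- The p < 0.001 knockout filter, the 20% inversion cap, the 1% knockdown
  step with 3 replicates and the top-10% hub rule are protocol constants
  of the emulated analysis; all are exposed as parameters.
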