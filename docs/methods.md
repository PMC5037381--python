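# Methods

## Model and procedure

Community detection is posed as the bi-objective minimization of the pair
(NRA, RC) over partitions of an undirected graph:

- `NRA(S) = − Σ_i L(S_i, S_i) / |S_i|` (negative ratio association),
- `RC(S) = Σ_i L(S_i, S̄_i) / |S_i|` (ratio cut),

with `L(A, B) = Σ_{i∈A} Σ_{j∈B} a_ij`. Both orientations of every edge are
counted, so `L(A, A)` counts each internal edge twice. Under this
convention the modularity density decomposes exactly:
`D(S) = Σ_i (L(S_i,S_i) − L(S_i,S̄_i))/|S_i| = −(NRA + RC)`. NRA rewards
dense community interiors, RC penalizes cross-community links; minimizing
both at once trades off resolution against separation, and the per-size
normalization avoids the degenerate all-in-one and all-singleton optima
that either objective alone would have.

The solver is a decomposition-based evolutionary algorithm with a
membrane-partitioned population:

1. **Decomposition.** `cell_num` weight vectors
   `λ_i = (i/(k−1), 1−i/(k−1))` turn the bi-objective problem into scalar
   subproblems via the Tchebycheff scalarization
   `g(x | λ, z*) = max_j λ_j |f_j(x) − z_j*|`. The reference point `z*` is
   the running component-wise minimum of every objective vector evaluated
   so far; it is initialized from the evaluated initial population (not
   ±∞), so first-generation scalarizations are already meaningful. The
   absolute value keeps terms nonnegative when `z*` later improves past a
   stored value. Weighted-sum scalarization is deliberately not offered:
   it cannot reach non-convex parts of a Pareto front, and nothing
   guarantees convexity here.
2. **Membranes.** Each subproblem owns a membrane holding
   `popsize / cell_num` solutions (3 at the defaults). Per generation each
   membrane draws one parent from itself and one from a membrane chosen
   uniformly inside its niche (the `niche` nearest subproblems by
   weight-vector distance, self included), applies two-point crossover
   (probability `pc`) and per-locus mutation (rate `pm`), evaluates both
   offspring, updates `z*`, and lets each offspring replace the membrane's
   worst member if strictly better under the membrane's own scalarization
   (best offspring first). Membrane sizes never change; elimination is
   replacement.
3. **Migration.** Once per generation every membrane's best solution (its
   scalarized minimum; ties go to the earliest slot) is offered to the two
   index-adjacent membranes. Since weight vectors are ordered, adjacent
   membranes are adjacent in objective space. A copy is accepted only when
   strictly better than the receiver's worst member under the *receiver's*
   weight — the strictness prevents the population collapsing to one
   genotype. The topology is a chain by default; `adjacency="ring"` joins
   the endpoints.
4. **Archive and selection.** Every evaluated solution is offered to a
   global archive kept mutually non-dominated (exact duplicates — same
   objective vector and same canonical partition — are rejected). After
   `maxgen` generations the reported clustering is the archive entry with
   maximal Newman–Girvan modularity Q, ties broken by fewer communities,
   then by lower NRA + RC. Q is the standard single-number quality score
   for reporting community structure, which is why it is the selection
   criterion rather than a third objective.

The baseline mode (`MOEAD`) is the classic decomposition algorithm: one
solution per subproblem (`popsize` of them), mating confined to the niche,
and each offspring replacing any niche member it improves upon in that
member's scalarization. Same encoding, objectives, archive and selection.

### Encoding

Solutions use the locus-based adjacency representation: allele `g[i] = j`
asserts nodes i and j share a community, and decoding takes connected
components of the graph `{(i, g[i])}` (union-find with path compression).
The community count is therefore an outcome, not a parameter. Alleles are
restricted to graph neighbours (isolated nodes point at themselves), which
guarantees every decoded community induces a connected subgraph and
removes a huge swath of meaningless genotypes; initialization, mutation
and crossover all preserve this closure. `encode_partition` (spanning-tree
parent pointers) inverts decoding for any partition with connected
communities and exists mainly so tests can plant known solutions.

## Parameters

| name | default | meaning |
|---|---|---|
| `popsize` | 120 | total population, split evenly over membranes |
| `cell_num` | 40 | number of membranes = number of subproblems |
| `niche` | 13 | neighbourhood size for mate selection (baseline: replacement too) |
| `pc` | 1.0 | crossover probability per mating |
| `pm` | 0.06 | per-locus mutation rate (expected `0.06·n` loci redrawn) |
| `maxgen` | 200 | generations |
| `adjacency` | chain | migration topology (`chain` or `ring`) |
| `random_state` | None | seed; a run is fully reproducible from it |

These defaults are the standard operating point for this algorithm family
(the baseline conventionally uses `popsize=100`, `niche=40`). All
stochastic steps draw from one `numpy.random.Generator` in a fixed order,
so identical seeds give byte-identical histories and partition files; this
is asserted in the suite.

## Numerical and design choices

- **Tie-breaking** is deterministic everywhere: scalarized ties go to the
  earliest slot, archive-selection ties to fewer communities then lower
  objective sum, oracle ties to fewer communities. Reproducibility was
  preferred over any stochastic tie policy.
- **No objective normalization.** NRA and RC live on different scales; the
  spread of weight vectors absorbs this. Normalizing would change which
  subproblem "owns" which front region but not the archive, which is
  scale-free (dominance only).
- **Crossover cut points** are drawn uniformly with replacement then
  ordered, so a single-locus swap (i = j) is possible.
- **Degenerate inputs**: edgeless graphs are rejected by the optimizer
  (modularity is undefined); self-loops are dropped and parallel edges
  collapsed to the max weight on read, with a logged count; empty
  communities raise. Weighted graphs are supported throughout the
  objectives, though the shipped benchmarks are unweighted.
- **Membrane "best"/"worst"** are defined by the membrane's own
  Tchebycheff value at the current `z*` — they are relative notions that
  sharpen as the reference point tightens.

## Synthetic data and what the tests show

The planted ℓ-partition generator draws equal-sized communities with
Bernoulli(p_in) edges inside and Bernoulli(p_out) between. The recovery
study uses 4 communities × 8 nodes, p_in = 0.9, p_out = 0.05 — a clearly
assortative but not disjoint regime (expected ≈ 101 internal + 19 bridge
edges) — and demands exact recovery (NMI = 1) on at least 4 of 5 seeds.
This emulates the block structure of small social networks; it does not
emulate heavy-tailed degree or community-size distributions, overlapping
membership, or weights, so passing says the optimizer recovers clean
planted block structure, not that it handles LFR-style heterogeneity.

The exhaustive oracle enumerates all set partitions (restricted-growth
strings, guarded to ≤ 12 nodes) and anchors correctness end-to-end: on a
corpus of connected graphs of ≤ 8 nodes the optimizer must hit the
enumerated maximum-Q partition exactly. The embedded Zachary karate club
(34 nodes, 78 edges) provides the real-data check: best-of-10 seeded runs
reach Q = 0.4198, this network's known modularity optimum, for both
algorithm modes. Small-instance runs in the suite use reduced populations
and 15–60 generations; the full-parameter karate runs are kept because
they are the headline result and finish in seconds each.

## Limitations

- The method is stochastic; single-seed results on larger networks vary,
  hence best-of-k reporting.
- Sequential by design: the seed-determinism contract forbids
  naive parallel evaluation.
- Undirected simple graphs only; no directed, bipartite or overlapping
  community support.
- Maximizing Q for final selection inherits Q's resolution limit; the
  archive retains the full front, so other selections can be applied
  downstream.
- `O(maxgen · popsize)` objective evaluations, each `O(m)`: networks in
  the thousands of nodes are minutes-scale, not interactive.
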