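# Methods

## Model and objective

`dysmod` frames active-module detection as combinatorial optimisation over
connected induced subgraphs of an undirected, unweighted, connected
interaction network in which every node carries two differential-expression
z-scores (one per experimental condition; genes without evidence score
exactly 0).

A node set *N* aggregates expression as `z_N = Σ_{i∈N} |z_i| / √|N|`. The
√|N| normalisation makes the score comparable across sizes: under a
standard-normal null the aggregate of n independent scores grows like √n, so
`z_N` behaves like a size-standardised signal strength. Absolute values make
the score direction-free — a module mixing up- and down-regulated genes is
as strong as a uniformly shifted one.

Two fitness functions couple expression with topology:

- **overlap mode** (one module *S* under both conditions):
  `F = z_S(1) + z_S(2) + ⟨C⟩(S)`, where ⟨C⟩ is the average local clustering
  coefficient of the subgraph induced by *S*. The clustering term rewards
  internally dense, community-like modules.
- **disjoint mode** (condition-specific modules *S1*, *S2*, disjoint):
  `F = z_S1(1) + z_S2(2) + Q(S1, S2)`, where *Q* is the Newman two-module
  modularity of the subgraph induced by `S1 ∪ S2`:
  `Q = (1/2E) Σ_{i,j same module} [A_ij − k_i k_j / 2E]`, with adjacency,
  degrees and edge count all taken from the induced union graph.

Both topological terms are bounded (⟨C⟩ ∈ [0,1], Q ∈ [−1,1]) while the
expression terms grow with signal, so topology acts as a tie-breaker among
comparably expressed candidates rather than dominating the objective. The
optimiser minimises `F̄ = 1/(1+F)`, a strictly decreasing transform of F.

Numerical conventions: nodes of induced degree < 2 contribute 0 to ⟨C⟩; a
disjoint union with no induced edges is degenerate and gets Q := 0 with a
warning; the within-module restriction in Q is part of the definition (the
unrestricted double sum cancels identically to zero and measures nothing).
⟨C⟩ and Q are computed on the induced subgraph, not on host-graph
neighbourhoods, so the fitness of a candidate depends only on the candidate
itself.

## The evolutionary search

Individuals are node sets of fixed size (a pair of disjoint sets in disjoint
mode; the two sizes may differ). All operators preserve the invariants
"connected induced subgraph, fixed size, disjointness" by construction:

- **initialisation** — randomised depth-first search from a uniformly chosen
  start node, stopped at the target size; on a connected host this always
  succeeds and repeated draws cover diverse regions.
- **mutation** (rate 0.9 per individual) — pick a random member whose removal
  keeps the remainder connected (checked by DFS, up to `mutation_max_tries`
  = 50 picks), then add a host-graph neighbour of a random surviving node
  (excluding current members and, in disjoint mode, the partner set). Since
  the replacement is adjacent to a survivor, insertion cannot disconnect the
  set. If no admissible move is found the individual is returned unchanged.
  In disjoint mode the swap is applied to each set independently.
- **crossover** (rate 0.1 per mated pair) — active only when the parents'
  corresponding sets share a node (their union is then connected): children
  are regrown inside the merged set by randomised DFS from random start
  nodes, preserving each parent's size. In disjoint mode the s1 and s2
  merges are regrown independently where they intersect; mutual disjointness
  is re-checked with bounded retries, else the parents pass through.
- **selection** — binary tournaments on F̄ (lower wins, ties uniform) fill the
  parent pool; the two best individuals of each generation are copied
  unmodified into the next (elitism), which makes the best-F̄ history
  non-increasing.

Generation schedule: evaluate → elitist copy → tournament selection →
crossover on consecutive parent pairs → mutation. Defaults (used by every
experiment here): 100 generations, population 200, crossover 0.1, mutation
0.9. Fitness values are cached per node set within a run; all randomness
flows from one `random.Random(seed)`, and nodes are mapped to dense integer
ids at load time so that set iteration — hence every seeded run and every
CLI output — is byte-reproducible across interpreter sessions (string hash
order is salted per process; integer hashing is not).

## Synthetic benchmark

The generator produces Lancichinetti–Fortunato–Radicchi community-structured
graphs (via `networkx.LFR_benchmark_graph`): power-law degrees (exponent 2,
cap max(n/10, 3⟨k⟩)), power-law community sizes (exponent 1.5, sizes 10–50),
and a mixing parameter giving the fraction of each node's edges that leave
its community. Note on naming: the mixing parameter is exposed as `mixing`
(LFR's μ); some of the module-detection literature calls the same quantity
γ. Defaults — 300 nodes, average degree 4–10 — emulate curated disease
interactomes of a few hundred genes with average degree ≈ 4.

Community-size exponent 1.5 rather than the boundary value 1: the networkx
generator requires exponents strictly above 1, and 1.5 sits in the canonical
benchmark's 1–2 range. All LFR knobs are exposed as parameters.

Connectivity: draws are retried (default 10 attempts) until the graph is a
single connected component; at average degree 4 a fully connected draw is
rare (degree-1/degree-0 tails), so the fallback extracts the largest
connected component of the best attempt — typically 90–97 % of nodes —
which preserves the degree distribution, at the cost of a slightly smaller
network.

Planting: the first differentially expressed community is the one whose size
is the largest not exceeding the mean community size; in disjoint mode the
second has the closest strictly larger size; in overlap mode the same
community is used for both conditions (ties broken uniformly). Planted
nodes draw `z ~ ±N(μ1=3, σ)` with a per-node random sign, all others
`z ~ N(μ2=0, σ)`, independently per condition.

**Well-posedness**: a benchmark is only meaningful if its ground truth is a
member of the search space, i.e. the planted communities induce connected
subgraphs. At low average degree the LFR wiring occasionally produces a
selected community that is internally disconnected — no connected-module
method could recover it exactly. `make_benchmark` therefore regenerates the
topology (bounded retries) until the planted communities are connected.

What the benchmark does *not* emulate: real interactomes have hubs far above
the n/10 degree cap, study-bias degree correlations, false-positive and
missing interactions, and z-scores that are correlated along pathways rather
than i.i.d. normal. Passing recovery tests therefore demonstrates that the
optimiser finds planted signal under idealised noise, not that experimental
modules are complete or exact.

## Recovery metrics

Prediction accuracy treats membership as a per-node binary classification
over all network nodes: `PA = 1 − (FN+FP)/(TN+TP)`; it equals 1 iff the
sets coincide and is symmetric in its arguments. Because the universe is
much larger than the module, PA is forgiving — a 20-node module missing 5
nodes in a 300-node network still scores ≈ 0.97.

Normalised mutual information compares whole partitions (module set(s) plus
background):
`NMI = −2 ΣΣ C_ij log(C_ij N / C_i· C_·j) / [Σ C_i· log(C_i·/N) + Σ C_·j log(C_·j/N)]`,
which equals `2·I(O;A)/(H(O)+H(A))`; the log base cancels (natural log
used). Conventions: `0·log 0 = 0`; two identical trivial partitions (one
group, or all singletons, where the denominator vanishes) are defined as
NMI = 1. NMI is the stricter metric: missing one node of a 20-node module
already costs several points.

Subnetwork significance: the observed `z_N` is compared with `n` random
connected subnetworks of the same size (randomised DFS from uniform starts),
reported as the add-one-smoothed exceedance fraction `(r+1)/(n+1)`. A
resampling null is used because no parametric null for DFS-sampled connected
sets is available in closed form.

## Expression front end

Per-gene tables (gene, raw p, log2 mean expression, log2 fold change) are
processed as: Benjamini–Hochberg step-up adjustment (statsmodels); DE
selection by `p_adj < 0.05`, `log2 mean expression > 6.64`,
`|log2 FC| > 1`. The fold-change filter is two-sided — down-regulated genes
must be eligible, otherwise no mixed-direction module could ever be found.
Z-scores of DE genes are the upper-tail normal quantile of their *raw*
p-value, `z = Φ⁻¹(1−p)` (p clamped into the open unit interval); all other
nodes score exactly 0. Since the fitness uses |z|, the missing sign is
immaterial; regulation direction is carried in reports, not in the score.

The disease network keeps every interaction between two DE genes plus every
non-DE "linker" (hidden) node with ≥ 2 DE interaction partners, together
with its DE-incident edges only (edges between two linkers are dropped —
linkers are included to witness indirect DE–DE paths, not to import
unrelated neighbourhoods), then restricts to the largest connected
component. Every retained linker keeps ≥ 2 DE neighbours in the output, and
the output is connected.

## Consensus across runs and sizes

Repeated runs across a size sweep (e.g. sizes 10–40 step 5, 30 runs per
size) are aggregated by node identification frequency: the fraction of all
runs whose best solution contains the node (all sizes pooled; per-component
frequencies available in disjoint mode). Nodes strictly above the frequency
threshold (default 0.3) form the consensus set; its largest connected
component is the reported consensus module, with ties broken by total
frequency mass and then lexicographically, so results are deterministic.

## Problem sizes used in the shipped experiments

The validation experiments run the full optimisation protocol (100
generations, population 200) on 300-node benchmarks with 5 independently
seeded runs per benchmark: the acceptance script covers the full 9 × 4
perturbation grid (180 runs, ≈ 8 minutes on one CPU); the test suite uses
the grid corners (10 benchmarks, 50 runs). Exhaustive-oracle optimality is
checked on 12–15-node graphs where all connected 4–5-node subsets can be
enumerated; formula-level oracles run on the complete graph atlas up to 7
nodes (clustering) and 6 nodes (modularity). These sizes were chosen so the
whole suite re-runs in minutes while every claim is still computed, never
asserted.

## Known limitations

- The optimiser needs the module size as an input; on real data the
  recommended protocol is the size sweep plus consensus, not a single size.
- Fitness weights expression and topology 1:1 with no tunable trade-off.
- The LFR fallback (largest component of the best draw) yields slightly
  fewer than the requested nodes at average degree 4.
- The empirical significance null (uniform connected subnetworks of equal
  size) is one of several defensible nulls; absolute p-values depend on it.
- Node identity is by case-sensitive symbol; no identifier mapping layer.
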