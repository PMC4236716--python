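# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `spanet`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Reconstruction by selective permissibility

The annotation collection table is the per-aspect union of the core
proteins' GO terms. "Match" is implemented as **non-empty intersection per
aspect**: a candidate needs at least one shared term in each of cellular
component, molecular function and biological process. Subset containment
would be far too strict — a table covering a few percent of the annotation
vocabulary must still be able to admit hundreds of proteins. Terms compare
as literal identifiers; no ancestor propagation over the GO graph is
performed (the package has no ontology-structure input), so annotations at
different granularity count as different terms. A protein with an empty
aspect can never be permissible. Core proteins bypass the rule but, like
everyone else, appear in the result only if they retain at least one
physical interaction inside the largest connected component;
"significantly small components are eliminated" is implemented as
keep-the-largest-component.

The reconstruction is a pure, non-iterative function of its inputs: the
admitted set is computed once from the fixed table, so the output is
independent of protein ordering, and enlarging the table per aspect can only
enlarge the admitted set (a property the suite checks on random table
perturbations).

## Eigenvector-centrality tuning

Centrality is the dominant eigenvector of the adjacency matrix, computed by
power iteration on `A + I`. The +1 diagonal shift makes every eigenvalue of
a bipartite (or near-bipartite) component strictly dominant in modulus
without changing the eigenvector, guaranteeing convergence where plain
iteration oscillates. Scores are non-negative and L2-normalized.
Convergence is declared when successive iterates differ by `< 1e-12` in max
norm — comfortably above the float64 noise floor (`n · eps`) for networks of
a few thousand nodes, and tight enough that the suite's dense-eigensolver
comparison holds to `1e-8` even on slow-mixing path-like graphs.

Graphs can carry several near-identical top eigenvalues — e.g. two equally
dense complexes hanging off the periphery. The dominant eigenvector is then
ill-conditioned and power iteration is asymptotically slow in a way no
stopping tolerance fixes. When the iteration budget (50 000) is exhausted
while the per-step drift is already below `1e-5`, the subspace-converged
scores are returned with a logged warning: they are deterministic,
normalized, and adequate for the significance test (which only asks whether
a node's observed score sits far from its randomized distribution).
A genuinely unconverged iteration raises an error with the iteration count.

The null model is the double-edge-swap randomization: `swap_multiplier × |E|`
swap *attempts* (default 10×), each replacing edges (a,b),(c,d) with
(a,d),(c,b) unless a self-loop or duplicate would result. Every node's
degree is preserved exactly; connectivity is deliberately not repaired
(disconnected randomizations are legitimate null draws; nodes outside the
dominant component receive near-zero centrality there).

Per node, the `R = 100` null scores are tested against the observed score
with a two-tailed one-sample t-test; `p < α = 10⁻⁴` (the 99.99% confidence
level) retains the node. The one-sample orientation — null sample versus
observed value as hypothesized mean — is the natural reading of "is this
node's centrality different from random networks?"; a two-sample variant
would need within-network replication that does not exist. Zero-variance
degenerate samples follow the t-test's limit: all null scores equal to the
observed value → not significant; constant but different → significant.
The tuned network is the induced subgraph on retained nodes, **not**
re-reduced to one component (a second sweep is left to the caller; the
topology stage summarizes the largest component and says so in the run log).

## Topology panel and hierarchical modularity

Shortest-path metrics come from breadth-first search over all sources,
local clustering is `2T(v)/(deg(v)(deg(v)−1))` with 0 below degree 2, and
betweenness is normalized by `(n−1)(n−2)/2`. The hierarchical-modularity
exponent `w` is fitted by ordinary least squares of `log₁₀ C(k)` on
`log₁₀ k`, where `C(k)` is the mean local clustering over raw integer-degree
bins; bins with `k < 2` or `C(k) = 0` are dropped before the log transform,
and fewer than three surviving bins is an error rather than a fit.
Logarithmic binning was considered and rejected: raw bins are the simplest
reproducible convention and the suite's noiseless-recovery test pins the
estimator exactly. The deterministic hierarchical reference network
(clique replication: a 5-clique whose four replicas' peripheral nodes link
to the original hub, iterated) has the analytic scaling `C(k) ~ k⁻¹`; the
fitted exponent on the 625-node instance must land within ±0.15 of 1.0.

## Dense-module detection

Vertex weight is `k_max · density(highest k-core of the closed neighborhood)`,
zero below the degree threshold; loops are excluded from density throughout.
Module growth starts at the heaviest unvisited vertex and examines neighbors
breadth-first (layers capped by max depth, all ties broken lexicographically
so results are reproducible). A neighbor joins when

1. its weight exceeds `(1 − node_score_threshold) × seed weight`
   (strict inequality — boundary equality is excluded), **and**
2. adding it does not decrease the running module score `density × size`,
   i.e. it brings at least `E/(n−1)` edges into the current n-member,
   E-edge module.

The second, density-preservation gate is this package's dialect decision.
Published descriptions of the algorithm are ambiguous about how expansion is
bounded, and the seed-weight gate alone freely crosses single-edge bridges
between equally dense regions: in a graph of two 6-cliques joined by one
edge, both bridge endpoints carry full weight, so a pure weight gate fuses
the cliques into one diluted module. With the density gate the two cliques
are reported separately at score 6.0 each, which exhaustive densest-subgraph
enumeration confirms is the right decomposition. The price is that module
*membership* is no longer globally monotone in the node-score threshold
(only weight-eligibility is); the suite tests the part that holds.

Haircut retains each module's 2-core (iterated removal of degree-1 members);
vertices trimmed by haircut are released for later modules, so a bridge
vertex swallowed early can still be examined elsewhere. Modules must contain
a k-core at the K-core threshold and at least 2 members; fluff is accepted
as a flag for interface compatibility but raises if enabled (it was disabled
in the analysis this package models). Scores are recomputed after haircut.
Reported modules are pairwise disjoint, ranked by score, then size, then
smallest member.

## Enrichment and candidate extraction

The reference universe is the analyzed network's proteins carrying at least
one process annotation ("whole annotation as reference set"); each module of
at least `min_module_size = 5` members is tested per process term present in
it, with `n` the module members inside the reference (members with no
process annotation cannot be tested and are excluded from `n`, keeping
`k ≤ n ≤ N` consistent). The hypergeometric upper tail is computed through
the survival function in log space; Benjamini–Hochberg runs within each
module's term family, and records with `q < 10⁻⁴` are reported. "Unknown
biological function" is operationalized as an empty process set or the root
process term (`GO:0008150`) alone — the two ways curation expresses
"unknown" — and such members of reported modules are the candidate list.

## Reporter transcription factors

Scoring is one-tailed on significance of change, without direction: the
inverse-normal transform uses the p-value only, and the aggregate
`Σz/√n` is compared against an **empirical** background (mean and SD of the
same aggregate over `background_samples = 10 000` random scored-gene sets
per distinct target-set size) rather than assuming N(0,1) — gene-level
z-scores are not normal under realistic signal mixtures. No multiple-testing
correction is applied across TFs; the raw 0.05 threshold is the published
procedure. Genes in the regulatory network without a p-value are excluded
from target sets and background alike. A background whose spread is at the
float-rounding scale (all scored genes identical) is treated as zero spread
and yields corrected score 0.

## Synthetic benchmark

The generator emulates the statistical structure each stage assumes — not
any particular organism's data:

- **Interactome**: preferential attachment (`n = 500`, 3 edges per new
  node), giving the heavy-tailed degree distribution the tuning and module
  stages expect. It does not emulate literature bias, false-negative edges,
  or evidence codes.
- **Planted modules**: three cliques of sizes 8, 9, 10 on low-degree nodes,
  each tied to the background by 1 to size/2 bridge edges to distinct
  partners. Sizes are graded deliberately: identical planted cliques give
  the adjacency spectrum several coinciding top eigenvalues, an artificial
  symmetry real complexes do not display, which makes node-level centrality
  ill-posed. Cliques are the strongest detector signal; weaker densities
  are a test parameter, not the default.
- **Annotations**: a core vocabulary of 8/8/12 terms per aspect covered
  exactly by the 14 cores; ~30% of non-cores are constructed permissible
  (≥ 1 core-vocabulary term per aspect), the rest have at least one aspect
  with none. Permissibility is augmented along shortest paths until every
  core and planted module sits in one admitted component, mirroring real
  seed networks that are essentially single-component. Each planted module
  shares a dedicated process term (its "function") so enrichment has a
  planted signal. ~5% of permissible proteins are "unknown function"
  (root-only process annotation; at least one per planted module), plus two
  off-network proteins with truly empty process sets. No GO-DAG topology is
  emulated, so passing tests say nothing about propagation effects.
- **Regulome/transcriptome**: 20 TFs × 20 targets; 3 active TFs whose
  targets draw p-values from a two-sided normal test with noncentrality 4;
  all other genes uniform. Only gene-level p-values are emulated, not
  intensities or replicate structure.

All randomness flows through seeded numpy generators; stage sub-seeds are
derived as fixed offsets from the benchmark seed, so one integer reproduces
everything, including byte-identical pipeline report directories.

## Problem sizes

The suite and the acceptance script run the pipeline at 500 proteins
(200 for pipeline-level unit tests), 100 null randomizations, 10 000
background samples, 200 TFs for the null-calibration check, and a 625-node
hierarchical reference network — sizes chosen so planted effects are far
from decision boundaries while the whole suite stays fast.

## Known limitations

- Permissibility is sensitive to annotation granularity; without DAG
  propagation, sparsely annotated proteins are under-admitted.
- The tuning t-test treats the null scores as independent samples; they
  share the degree sequence, so the test is approximate.
- The module detector is greedy and order-sensitive by construction;
  determinism is obtained by lexicographic tie-breaking, not by global
  optimality.
- Enrichment ignores term–term dependence (parent/child double counting).
- The reporter background resamples from the scored-gene pool, so extreme
  target-set sizes (close to the pool size) have compressed backgrounds.
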