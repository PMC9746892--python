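# Methods

This note records what `ppintopo` computes, the conventions and numerical
choices behind it, and what the synthetic test surface does and does not
establish about real interaction data.

## Data model and cleaning

A PSI-MITAB file (15-column 2.5 or 42-column 2.7 layout, auto-detected by
column count) is reduced to typed records keeping the two primary interactor
accessions, the interactor molecule classes (2.7 only), source taxa, the
detection method and publication fields verbatim, and the `intact-miscore`
confidence. The first identifier in the primary-id column defines node
identity; alternative accessions and aliases are ignored, and no cross-
database identifier mapping is attempted. Missing fields (`-`) map to
absent.

Network construction collapses records onto unordered canonical pairs
(lexicographic order). The first record of a pair creates the edge; later
records count as duplicates (same orientation) or reversed repetitions
(opposite orientation). Self-pairs never become edges — a degree defined as
the number of neighbours cannot count them — but their nodes are kept and
every self-loop record is logged, so the repetition accounting of a raw
export can be reconstructed from the build log. Non-protein and
foreign-taxon interactors are *kept* by default (they are part of what the
source database asserts; flagging is the analysis) and can be dropped
explicitly. Analyses that need connectivity run on the largest connected
component; component-size ties are broken by the component containing the
lexicographically smallest node, and all argmax/ranking ties throughout the
package break lexicographically by node id, so every result is
reproducible.

## Measures

Degrees, the mixing matrix and the impact curves are exact counts.
Conventions worth stating:

- **Assortativity.** r is the Pearson correlation of degrees across the 2L
  directed edge ends, computed from the mixing-matrix accumulator
  (r = (Σ x·y·e_xy − μ²)/(Σ x²·a_x − μ²), μ = Σ x·a_x). On any regular
  graph the variance is zero and r is reported as undefined (`None`), not
  as a number. This scalar (Pearson) form is the field-standard degree
  correlation; the categorical trace-form coefficient sometimes written for
  discrete mixing matrices is a different statistic and is not used.
- **Betweenness** is normalized by (N−1)(N−2)/2 and **closeness** is
  (N−1)/Σd, so both live in [0, 1] and are comparable across network sizes.
  Shortest paths are unweighted hop counts. Both are delegated to igraph's
  exact C implementations; the test suite holds them to handwritten
  brute-force path-enumeration oracles.
- **Eigenvector centrality** is computed by power iteration on A + I,
  started from the uniform vector, normalized to unit Euclidean norm, and
  declared converged when successive iterates differ by < 1e−10 in
  max-norm (at most 10⁵ iterations; non-convergence raises an error
  carrying the last iterate). The +I shift leaves the principal eigenvector
  unchanged while making the dominant eigenvalue strictly largest in
  magnitude, so the iteration also converges on bipartite graphs (e.g.
  stars), where iteration on A alone oscillates between the ±λ eigenspaces.
- **Clustering** is 2L_i/(k_i(k_i−1)) with Cl = 0 assigned for k < 2, which
  keeps the network mean over *all* nodes well defined.
- **ANND** excludes isolated nodes (no neighbours to average over) and logs
  them; normalized ANND divides both the degree axis and the ANND axis by N.

## Power-law fitting

The degree tail is fitted with the standard discrete maximum-likelihood
procedure: for every candidate cutoff k_min (each distinct degree with at
least 8 tail points and two distinct tail values), γ maximizes the discrete
log-likelihood −n ln ζ(γ, k_min) − γ Σ ln k (bounded scalar optimization,
tolerance 1e−6, checked in tests against an exhaustive γ grid of step
0.001); the cutoff minimizing the KS distance between the empirical tail
CDF and the fitted Hurwitz-zeta CDF wins. Goodness of fit uses a
semiparametric bootstrap — each synthetic sample draws tail points from the
fitted law (exact inverse-CDF sampling through the Hurwitz-zeta survival
function) and body points by resampling the observed sub-cutoff values,
then gets the full refit — and p is the fraction of synthetic KS distances
at least as large as the observed one; fits with p > 0.1 are called
plausible. The default bootstrap count is 1000; tests and the acceptance
script use smaller counts or skip it, since the exponent and cutoff do not
depend on it. Fewer than 50 observations or a constant sequence is an
error; a chosen tail of fewer than 50 points sets a warning flag. On
synthetic samples the estimator recovers γ = 2.5 within ±0.05 at n = 10⁴
and ±0.15 at n = 10³.

## Simulations

**Targeted attacks** use a *static* ranking: the centrality is computed
once on the intact network and nodes are removed in descending order (ties
ascending by id). Static ranking is the default because it is the
reproducible, order-independent reading of "sort and remove", and it is
what all reported decomposition points use; adaptive re-ranking after every
removal is available as an option. The relative LCC size is recorded after
every single removal. Trajectories are computed exactly by a reverse
union–find sweep (removals processed backwards as insertions, tracking the
maximum component size), costing O((N+L)·α) per trajectory instead of
O(N·(N+L)) for naive recomputation; the naive recomputation remains in the
tests as the oracle. **Random failures** average MC independent uniformly
random orders (default MC = 100; run r uses seed + r). The
**decomposition point** d is the smallest recorded f with S(f) < 0.01; the
threshold is configurable and f = 1 always qualifies.

**Failure cascades** flag nodes, never remove them: the trigger compares
the failed fraction of a node's neighbours against F using the node's
original degree, with an inclusive ≥ F comparison (a node whose single
neighbour failed must itself fail at F = 1). Because failure is monotone,
the fixed point is unique and sweep-order independent — the default
implementation propagates through a queue in linear time, and an explicit
`sweep_order` reproduces the literal repeated-sweep procedure for the
order-invariance tests. The all-seeds screen counts a seed as propagating
when its final failed set has at least 2 nodes, and reports P_max with all
argmax seeds.

## Synthetic study conditions

The fixture generators define the conditions under which the package's
claims are verified. Analytic families (star, clique, path, cycle) carry
closed-form values for every measure. The Barabási–Albert generator uses
the repeated-nodes urn form of preferential attachment (bit-reproducible
for a given seed; L = m(N−m) by construction) at N = 1000, m = 2 — a size
at which the scale-free attack/failure contrast (d_degree < d_random − 0.2
across 20 seeds) is already unambiguous while every simulation runs in
milliseconds. Erdős–Rényi and Watts–Strogatz cover the homogeneous and
small-world regimes. Synthetic MITAB files inject duplicates (every record
once), reversed pairs (every second edge), and configurable numbers of
self-loops, non-protein interactors, foreign-taxon interactors and missing
scores, with a ground-truth manifest of the exact post-cleaning N, L and
anomaly counts; metadata is a single publication/method by default
(emulating single-experiment datasets) or varied per record.

What passing on these fixtures does **not** show: synthetic MI scores are
uniform-with-holes, not bimodal as in real curated sets; the generators
produce no correlated annotation structure (e.g. method–confidence
coupling); and desk-scale graphs cannot exhibit the slow crossover
behaviour of 10⁴-node interactomes. Claims about real data require running
the pipeline on a real export (the human-reference-interactome reproduction
test does exactly that when the IntAct IM-25472 download is present at
`data/IM-25472.mitab`).

## Bias screen

The flag thresholds — one hub on > 15 % of links, γ outside (2, 3), one
method > 90 % of records, one publication > 50 %, r > 0 — are configurable
defaults distilled from observed biased-dataset archetypes, not prescribed
constants; the report always carries the raw observed values alongside the
flags, and each flag's value is read from the report fields rather than
recomputed.

## Known limitations

- No PSI-MI XML, no live database queries, no ontology resolution beyond
  verbatim term text, and no identifier unification across databases: two
  accessions for the same protein stay two nodes.
- Networks are unweighted and undirected; MITAB directionality and the MI
  score do not enter the topology (the score is summarized, not used as an
  edge weight).
- Edge-removal attacks, weighted cascade thresholds and recovery dynamics
  are out of scope.
- The betweenness computation is exact (no sampling), so attack orderings
  on networks beyond ~10⁵ edges become the dominant cost.
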