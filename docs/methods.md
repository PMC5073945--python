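# Methods

## Model

The aligner treats the two PPI networks plus their cross-network
similarity edges as a single weighted graph and scores node
correspondence by how much stationary random-walk traffic each cross edge
carries. The assumptions this rests on:

- **Interactions are undirected and positively weighted.** Weights are
  interpreted as interaction confidence; an unweighted edge list means
  weight 1. Self-loops are discarded — the walk models moves between
  distinct proteins.
- **Similarity scores are non-negative and sparse.** Zero or negative
  entries carry no information and are dropped at parse time, so the
  similarity support defines the candidate pair set: a pair with no
  similarity entry can never be aligned. With BLAST bit scores this is the
  natural regime.
- **Correspondence ∝ stationary flow.** The walker's cross-network
  conditionals are the row-/column-normalised similarity matrix, so the
  flow through (u, v),
  `c(u,v) = π(u)·Pr[v|u] + π(v)·Pr[u|v]`,
  grows with the pair's own similarity and with the stationary mass that
  consistent neighbourhoods concentrate on u and v. Topology enters
  through π and through the consistency transformation, not through the
  conditionals.

### Making the transition matrix stochastic

Stacking the four blocks as written gives rows of mass 2 wherever a node
has both intra-network neighbours and similarity partners, which is not a
stochastic matrix and has no stationary distribution. Each assembled row
is therefore a convex combination: `block_mix` (default 0.5) on the intra
block and `1 − block_mix` on the cross block when both are active, the
single active block unscaled otherwise, and the uniform distribution over
all nodes for rows with neither (isolated, similarity-free proteins).
Equal block weighting is the minimal correction; `block_mix` is exposed
for sensitivity analysis. The uniform "teleport" rows affect no
correspondence score directly (flow support equals similarity support)
but keep the matrix stochastic.

### Stationary distribution

Power iteration from the uniform start vector, stopping when the L1
change falls below `tol` (default 1e-10) or at `max_iter` (default
10 000, then a warning is logged, the model is flagged non-converged, and
the CLI exits with code 3). No damping or global teleportation is added:
if the integrated graph is disconnected, π depends on the start vector,
and the uniform start is fixed as the contract. A genuinely periodic
component (a purely bipartite fragment with unequal sides — possible only
when a connected set of proteins has similarity edges but no interactions
at all) oscillates and trips the non-convergence warning; realistic
inputs, where most proteins interact, do not produce this.

### Consistency transformation and thresholding

`C̃ = α·C + (1−α)·P_X C P_Yᵀ` with α = 0.9 lets a pair inherit a fraction
of its neighbours' correspondence — pairs whose neighbours also
correspond are reinforced. Because the transformation also leaks score
into spurious neighbour pairs, C̃ is cut at β = the 90th percentile
(linear interpolation between order statistics) of its **positive**
entries; entries whose raw flow was already positive survive regardless,
at their transformed value. Computing the percentile over positive
entries only is deliberate: the matrix is sparse, and a percentile over
all |𝒰|·|𝒱| cells would be 0 and threshold nothing. For α > 0 the
thresholded support therefore contains the raw support exactly; at α = 0
a raw-support entry whose transformed value is exactly zero vanishes as a
structural zero (its score is 0 either way).

One property sometimes expected of the transformation does **not** hold:
its total mass. `Σ(P_X C P_Yᵀ) = c_xᵀ C c_y` where `c_x`, `c_y` are the
*column* sums of the row-stochastic intra matrices; these equal 1 only on
regular graphs, so on irregular networks the transformed total can exceed
or fall short of ΣC. The tests assert exact preservation on regular
(cycle) networks and entrywise agreement with a brute-force oracle
instead.

### Matching

The final one-to-one mapping is the assignment-problem optimum on the
thresholded scores, computed with `scipy.optimize.linear_sum_assignment`
and cross-checked in the tests against exhaustive permutation
enumeration. Zero-score pairs are never emitted — a pair with no
correspondence evidence is left unaligned rather than matched at zero
weight — so the output is a partial matching on rectangular inputs.
Determinism: matrices are always indexed in first-appearance node order
and the solver is deterministic for a fixed matrix, so equal-weight
optima resolve reproducibly. Note that co-optimal matchings genuinely
occur on symmetric inputs (e.g. identical paths under uniform
similarity, where same-degree targets tie exactly); the contract is
optimal total weight plus reproducibility, not a particular tie winner.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `alpha` | 0.9 | fraction of the raw flow kept in the PCT; 1 disables propagation |
| `beta_percentile` | 90 | percentile of positive transformed scores used as the sparsification threshold |
| `block_mix` | 0.5 | intra-block weight in the assembled walk (cross block gets the complement) |
| `tol` | 1e-10 | L1 stopping tolerance of the power iteration |
| `max_iter` | 10 000 | power-iteration cap |
| `ic_min` | 2 bits | minimum term information content for GOC/COI |

All are dimensionless. `alpha` and `beta_percentile` defaults are the
method's standard operating point; `tol` is far below any score
difference that could change a matching.

## Evaluation metrics

- **CN / SPE**: a pair is correct when the two proteins share an
  orthology-group label; pairs with an unlabeled protein are removed
  before counting, and SPE = CN / retained (flagged undefined, reported
  0, when nothing is retained). Shared-label is interpreted as non-empty
  intersection, since proteins may carry several group labels.
- **IC**: `−log2(|c| / |root(c)|)` computed from the supplied annotation
  corpus itself — |c| proteins carrying the term, |root(c)| proteins
  under the term's root. No ontology-graph traversal: the root is an
  input column, which keeps the metric self-contained.
- **GOC**: sum over aligned pairs of the Jaccard index of their term
  sets after removing terms with IC < `ic_min`; pairs left with an empty
  set on either side are removed.
- **CI / COI**: edges of X whose aligned images are edges of Y, counted
  once per undirected edge (counting ordered pairs would exactly double
  both numbers and change no comparison); COI keeps only edges whose
  both endpoint pairs have strictly positive filtered Jaccard.

## Synthetic generator

`generate_pair` emulates a pair of species networks descended from a
common ancestor: an Erdős–Rényi graph (default 100 nodes, expected degree
6 — the sparse regime of real PPI data) is copied twice; each side
independently loses 10 % of nodes and has 10 % of its surviving edges
flipped (each edge deleted with probability f/2 and a binomial f/2
fraction of random absent edges inserted, so the expected flip count is
f·|E|). Ground truth is the ancestor nodes surviving on both sides. Every
true pair receives a similarity score from a gamma(2) distribution with
mean 100, and spurious entries are sprinkled at 5 % density with mean 60
— bit-score-like scales with enough tail overlap that a noticeable
fraction of spurious scores beat true ones, which is exactly the regime
where a sequence-only matcher errs and topology can arbitrate. One
integer seed drives all sampling; replicate k of an ensemble uses
seed + k.

What the generator does **not** emulate: duplication–divergence topology,
degree-dependent deletion bias, many-to-many orthology (gene
duplications), correlated noise between similarity and topology, and the
extreme size/degree asymmetry of real cross-species comparisons (for
example, a 452-interaction network against a 43 757-interaction one).
Passing tests on this ensemble demonstrate the pipeline's mathematical
contracts and the direction of the topology benefit at desk scale, not
performance magnitudes on database networks.

## Numerical choices and degenerate inputs

- Duplicate edge or similarity records keep the maximum weight
  (conservative merge of redundant interaction records).
- Isolated nodes keep all-zero intra rows until assembly; empty
  similarity tables produce an empty alignment with a warning rather
  than an error.
- Row normalisation is exact to a few ulp; the stochasticity and
  conservation contracts are asserted at 1e-12 / 1e-10 in the tests.
- Percentile: linear interpolation (`numpy.percentile` default), fixed
  for determinism.
- Problem sizes in the tests and the acceptance script — 100-node
  ensembles, 50-instance contract sweeps, 20-seed recovery comparisons,
  ≤ 7-dimension exhaustive matching oracles — are chosen so each
  property is measured at full strength while the whole verification
  suite runs in seconds.

## Known limitations

- Two networks only; the block structure does not extend to N-way
  alignment in this implementation.
- One-to-one output only — no many-to-many mode, so genuine paralog
  families are represented by a single pair.
- No input format beyond whitespace/tab-separated edge lists and tables
  (no MITAB/OBO); similarity scores must be precomputed.
- The dense assignment solve is O(n³) in the smaller node set; it is
  instant at benchmark scale and acceptable for IsoBase-sized networks,
  but a sparse auction solver would be preferable for much larger inputs.
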