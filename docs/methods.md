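# Methods

## Model

Given a connected simple unweighted graph *G* = (*V*, *E*) with *n* nodes
and *m* edges, the method reduces overlapping community detection on nodes
to disjoint clustering of edges. A *cover* is a family of *k* node subsets
that may overlap and need not exhaust *V*. The pipeline:

1. **Line graph.** *L(G)* has one vertex per edge of *G*; two vertices are
   adjacent iff the edges share an endpoint. |V(L)| = m and
   |E(L)| = Σ_v C(d_v, 2). Edges are kept in canonical (sorted-pair,
   lexicographic) order so every downstream index is deterministic.
2. **Distance on L(G).** Either commute distance
   d_cm(i,j) = vol(G)·r(i,j), where r(i,j) = L⁺_ii + L⁺_jj − 2L⁺_ij is the
   effective resistance from the Moore–Penrose pseudoinverse of the
   combinatorial Laplacian, or the amplified commute distance
   d_amp(i,j) = r(i,j) − 1/d_i − 1/d_j + 2w_ij/(d_i d_j), which removes the
   degree-dominated component that makes raw commute distance uninformative
   on large graphs. The diagonal is 0 by convention. d_amp is **not**
   clamped: on small graphs off-diagonal entries can be 0 (e.g. the end
   pair of a 3-path) or negative; the medoid solvers accept such matrices.
3. **k-median.** Choose k medoid vertices of L(G) minimising the summed
   distance of every vertex to its nearest medoid.
4. **Belonging coefficients.** F(i,c) = (edges at node i in cluster c)/d_i;
   rows sum to exactly 1 because the edge clustering is a partition.
5. **Threshold.** Node i joins community c iff F(i,c) ≥ θ (inclusive).
   Since row sums are 1, a node can exceed θ in at most ⌊1/θ⌋ clusters:
   overlap is *non-increasing* in θ, and nodes that reach θ nowhere are
   reported in `unassigned` rather than force-assigned. The fractional
   matrix (which satisfies the row-sum identity) and the thresholded cover
   are both exposed, because the binary cover intentionally does not
   satisfy it.

The method ignores edge weights by construction (the line graph's vertices
are edges, not weighted objects); weighted, directed and multigraph input
is out of scope and rejected.

## Solvers

**Exact.** When C(m,k) is at or below a configurable budget (default 10⁷
candidate sets) the solver enumerates all medoid sets, walking prefixes of
size k−1 recursively and batching the last medoid in numpy; sets are
visited in lexicographic order and only strict improvements kept, so the
lexicographically smallest optimal set is returned — the tie rule that
pins down which of several symmetric optima a run reports. Above the
budget it solves the standard p-median integer program (minimise
Σ d_ij·y_ij s.t. Σ_j y_ij = 1, y_ij ≤ x_j, Σ x_j = k; x binary, y
continuous — optimal basic solutions are integral in y) with HiGHS via
`scipy.optimize.milp`. The MILP path certifies the same optimal objective
(cross-checked in tests) but returns whichever optimal medoid set the
solver lands on, deterministically.

**CLARANS.** Randomised local search: `numlocal` restarts (default 4) from
uniformly random medoid sets; each iteration samples a random
single-medoid swap and accepts the first improvement, declaring a local
optimum after `maxneighbor` consecutive failures, with
maxneighbor = max(250, ⌈0.0125·k·(m−k)⌉) following the heuristic's
original parameter recommendation. All randomness flows from one seed
(`numpy.random.default_rng`), making runs bit-reproducible.

**Assignment ties** go to the medoid with the smallest index, and every
medoid is self-assigned even when another medoid sits at distance 0 (the
amplified distance can produce distinct points at distance 0).

## Numerical choices

- Pseudoinverse rank cutoff: eigenvalues below 1e−9 × λ_max are treated as
  null. Resistance matrices are symmetrised (½(R+Rᵀ)) and the diagonal
  zeroed to remove O(1e−16) eigensolver noise.
- Disconnected input is an error naming the components, not a
  per-component computation: resistance across components is infinite and
  the medoid step needs a single finite metric space.
- Duplicate edges collapse with a warning; self-loops are rejected.
- Exact-solver optimality comparisons use strict `<` on float objectives;
  on discrete instances with exactly representable ties the lexicographic
  rule is exact, on generic instances ties are broken by floating-point
  comparison.

## Cover metrics

- **ONMI (LFK)** — default: each community is a binary membership variable
  over the universe; H(X_k|Y) is minimised over Y's communities subject to
  the validity constraint h(n11)+h(n00) ≥ h(n01)+h(n10) (falling back to
  H(X_k)); the score averages per-community normalised conditional
  entropies from both sides. A zero-entropy community (the full universe;
  empty ones are dropped) contributes 0, the 0/0 → 0 convention of the
  standard scorers.
- **ONMI (max)** normalises the mutual information by max(H(X), H(Y)) with
  the same conditional-entropy machinery. The two variants are *not*
  interchangeable; comparisons must use one consistently. The max variant
  reproduces to 1e−4 the published karate-club score for a
  one-node-off cover (see "Known limitations").
- **Omega index**: chance-corrected agreement of per-pair co-membership
  multiplicities; the degenerate obs = exp = 1 case returns 1.
- **Best-match F1** is symmetrised (mean of both directions) so it is a
  true comparison metric.
- **Cover statistics**: average internal degree = mean 2m_S/n_S;
  normalised cut = mean of cut(S)/vol(S) + cut(S)/(vol(G) − vol(S)), with
  a degenerate community (vol 0 or vol(G)) contributing 0 with a logged
  warning. Universe for the comparison metrics = all graph nodes;
  unassigned nodes simply belong to no community.

## Synthetic generators — what they emulate

- `grid_graph` — the featureless r×c lattice used as a null benchmark
  (8×8: 64 nodes, 112 edges, clustering coefficient 0).
- `planted_partition(l, g, p_in, p_out, seed)` — l disjoint groups of g
  nodes, independent Bernoulli edges (p_in within, p_out between), ground
  truth = the groups. Per-pair sampling, not fixed edge counts.
- `sbm_graph(sizes, probs, seed)` — general block model with a symmetric
  block-probability matrix.

The recovery benchmark uses 4 groups of 8 at p_in = 0.9 / p_out = 0.05:
strong assortative structure at a size (≈120 line-graph vertices) where
the exact solver finishes in seconds. These generators produce disjoint,
equal-sized ground truth with independent edges; they do not emulate
degree heterogeneity, overlapping ground truth, or local clustering of
real networks, so perfect recovery here demonstrates correctness of the
pipeline, not performance on real data.

Problem sizes throughout the test suite (line graphs ≤ 120 vertices,
oracle graphs ≤ 10 nodes, 20-seed recovery batches) are chosen so every
check certifies against exhaustive or closed-form oracles while the whole
suite stays in the low minutes on one CPU.

## The lattice example and the role of θ

On the 8×8 lattice the exact k = 4 optimum (identical for both distances,
objective 31651.77 under commute distance) is a *pinwheel* edge partition:
four congruent clusters of 28 edges. Its seam nodes hold 1/3 of their
edges in a neighbouring cluster, so:

- θ = 0.5 (default): four equal **disjoint** 16-node communities;
- θ ≤ 1/3 (e.g. 0.3): the seam nodes join both clusters — four equal
  communities, each overlapping exactly two others; k = 2 likewise gives
  two equal overlapping halves.

This is a design-relevant subtlety: the axis-aligned edge partition
(horizontal edges of the top rows, etc.), which *would* overlap at
θ = 0.5, costs strictly more (≥ 34360 under commute distance) and is
therefore never returned by an exact solver. We verified the arithmetic
independently (resistance against `networkx.resistance_distance` and
Kirchhoff-minor determinant ratios; the solver against brute-force
enumeration). Published illustrations of overlapping lattice covers are
consistent with the pinwheel optimum at θ in (1/4, 1/3].

## Known limitations

- The exact solver's lexicographic tie-break holds on the enumeration
  path only; the MILP path returns one (deterministic) optimal set.
- k-median landscapes of small real networks have near-ties: on the
  karate club the certified commute-distance optimum at θ = 0.45 differs
  from the two-faction truth by one moved and one overlapping boundary
  node (ONMI-max 0.757, F1 0.956), while a neighbouring near-optimal
  medoid pair reproduces the published 0.918. Scores this close to ties
  should be read as families of solutions, not point values.
- Commute distances need a dense eigendecomposition: O(m³) in the number
  of graph edges. Practical exact solving tops out around a few hundred
  edges; beyond that use CLARANS, and beyond ~10⁴ edges the distance
  computation itself dominates.
- Weighted/directed graphs, LFR/FARZ generators, and wrappers around
  third-party detection methods are deliberately out of scope.
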