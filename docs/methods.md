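# Methods

## The arithmetic-harmonic cut

For a complete weighted graph whose weights are pairwise distances
w(u, v) > 0, the package scores a bipartition (V₁, V₂) by

    f = cut_sum × intra_recip,
    cut_sum    = Σ { w(u, v) : u ∈ V₁, v ∈ V₂ },
    intra_recip = Σ { 1 / w(u, v) : u, v on the same side }.

The product form makes f scale-invariant (multiplying every distance by
c > 0 multiplies cut_sum by c and intra_recip by 1/c), which a
distance-based objective should be: the clustering must not depend on the
measurement unit. A side with at most one vertex contributes nothing to
the harmonic term, so the unique split of a two-vertex graph has value 0.
The combination of the two terms is a single pluggable function
(`ahcut.graph.combine_terms`), so an alternative reading (e.g. a weighted
sum) can be swapped in without touching the solvers; the product is the
default everywhere and the only form the tests assert.

The decision variant asks whether some bipartition reaches a rational
threshold k/l given by two positive integers (`DecisionTarget`). The
comparison allows 1e-12 relative slack to absorb float accumulation in f;
the threshold itself is exact.

### Degenerate inputs and numerical guards

- **Zero distances.** Identical objects would make the harmonic term
  undefined, so `build_graph` clamps off-diagonal entries below
  `weight_floor` (default 1e-9) up to the floor and logs a warning rather
  than merging duplicates or failing.
- **Validation.** Matrices must be square, symmetric within 1e-8 (the
  worst violating entry is reported; sub-tolerance asymmetry is averaged
  away), with zero diagonal and no negative entries.
- **Incomplete graphs.** Graphs built from edge lists may lack pairs;
  absent pairs contribute to neither term. Matrix-built graphs are always
  complete.
- **Improvement comparisons** in all local searches use strict `>` with
  1e-12 relative slack to prevent float-noise cycling.
- **Side-swap symmetry** is exact (not merely within tolerance): the
  evaluator derives the cut term from the total weight minus the two
  within-side quadratic forms, whose floating-point sum is commutative.

## Solver stack

### Exact backtracking

All 2^(n−1) − 1 non-trivial bipartitions are enumerated with the first
vertex pinned to side 1 (the objective is symmetric under side swap). A
binary-reflected Gray code orders the walk so consecutive assignments
differ by one vertex, giving O(n) incremental updates per step; any
candidate optimum is re-evaluated from scratch so drift cannot decide a
winner or a tie. Ties are broken toward the lexicographically smallest
side-1 label set. The recursion dispatcher uses enumeration up to
`exact_threshold` (default 15, ~16k evaluations, well under a second); a
hard cap of 22 (~2M evaluations) guards against accidental exponential
blow-ups.

### Greedy construction

Seed: the maximum-weight edge, one endpoint per side (ties broken by
lexicographic labels). Loop: among unassigned vertices pick the one with
the largest total weight to the assigned set, and place it on the side
that yields the larger partial objective (ties to side 1). The partial
objective treats singleton sides uniformly (harmonic contribution 0). On
disconnected graphs every component with edges contributes a seed pair
first, and isolated vertices — which touch neither term — are appended to
side 1 at the end. The vertex-selection and side-choice rules are the
natural differential-greedy instantiation consistent with the seed rule;
the selection criterion is the package's design choice and is kept local
to one helper so alternatives (max single edge, fixed order) can be added
behind a flag if needed.

The randomised variant used for population (re-)initialisation draws the
seed edge uniformly from the top decile of edges by weight and breaks
selection ties uniformly at random; it is reproducible per seed.

### Fixed-parameter decision procedure

`fpt_decide` follows greedy localisation: if the greedy partition reaches
the threshold it is returned as a Yes-certificate; otherwise the instance
is settled exactly by enumeration. The theory bounds the residual
instance when greedy fails; since that quantitative bound is not part of
this implementation, the fallback is simply enumeration under the hard
cap, which covers every desk-scale instance and keeps the procedure in
exact agreement with `enumerate_optimum`.

### Memetic algorithm

- **Population**: a complete ternary tree, depth 3 → 13 nodes (a standard
  size in the pocket/current literature this design follows). Each node
  holds a *pocket* (best-ever) and *current* (working) solution; pockets
  swap with currents when beaten, and pockets swap along tree edges until
  every parent dominates its children, so the root pocket is the global
  best. Initialisation: deterministic greedy at the root, randomised
  greedy elsewhere.
- **Crossover** (differential greedy): child orientation is aligned to the
  parent by agreement count, agreeing vertices seed the offspring, and the
  disagreeing remainder is re-filled by the greedy loop with rng tie
  breaks. An empty seed side is re-seeded from the heaviest edge among
  unassigned vertices. Every generation recombines each (parent pocket,
  child current) pair in level order.
- **Local search** (VNS): the order-k neighborhood flips exactly k vertex
  sides. k = 1 scans the whole neighborhood via incremental evaluation
  (vectorised over vertices); k ≥ 2 samples `vns_samples` (default 100)
  random k-subsets, evaluated in one batched quadratic form. The first
  strictly improving neighbor becomes the incumbent and k resets to 1;
  the search stops when k > `k_max` (default 3 — single and double flips
  dominate improvement in bipartitioning, the third order is a cheap
  escape hatch). Flips that would empty a side are excluded.
- **Diversity**: after `stagnation_generations` (default 20) without
  improvement of the best value, the best individual is kept and the rest
  of the population is re-initialised from randomised greedy starts.
  `max_generations` (default 200) bounds the run.
- **Reproducibility**: one run seed fans out into named independent
  substreams (init, crossover, vns, restart) via hashed
  `numpy.random.SeedSequence` spawn keys, so components are individually
  reproducible and run logs of equal-seed runs are identical.

### Recursive clustering

`build_dendrogram` applies the size-dispatched best split, recurses on the
induced subgraphs of both sides, and stops at single vertices, producing a
full binary tree whose internal nodes carry their split value. Children
are ordered by smallest member label, making Newick output byte-stable.
`cut_tree(root, k)` repeatedly expands the frontier node with the largest
split value (ties: smallest member label) — the natural way to extract a
k-cluster partition from a value-annotated divisive tree; consecutive cuts
differ by exactly one expansion. No early-stopping quality criterion is
applied: recursion always reaches single vertices, and flat clusterings
are a view on the finished tree.

## Distances

`centered_correlation_distance` computes d(x, y) = 1 − r(x, y) over
samples, with r the (mean-centred) Pearson correlation of gene vectors;
entries lie in [0, 2] with zero diagonal, and the uncentred (cosine)
variant is an explicit flag. Zero-variance samples are rejected by name.
Missing expression values are rejected rather than imputed — silent
imputation would corrupt benchmark comparisons. All supplied genes are
used; filtering is the caller's concern.

## Synthetic data

`generate_expression` draws three groups of samples from multivariate
normals with diagonal covariance σ²·I that differ only in their mean
vectors: group g owns a private block of `n_signature` genes, the first
`n_down` at mean `mu_down` and the next `n_up` at `mu_up`, all other genes
at mean 0. Defaults — group sizes (30, 15, 15), 500 genes, 30 signature
genes per group (10 down at −1, 20 up at +1), σ = 0.5 — model one
predominant disease subtype with two rarer ones, a ±2σ per-gene shift
being a realistic strong-marker effect size. At these settings the mean
within-group centred-correlation distance is ≈ 0.81 versus ≈ 1.0 between
groups, a separation of roughly four standard errors per pair at 500
genes: clearly recoverable, but far from trivial for objectives that
mishandle unequal cluster sizes.

What the generator does *not* emulate: technical artifacts (batch
effects, dropout, heteroskedastic genes), correlated gene blocks, or
non-normal marginals. Passing the recovery tests therefore demonstrates
that the solver stack optimises its objective well and that the objective
separates mean-shifted groups in correlation space — not that the method
is robust to real-data noise structure.

`planted_partition_graph` skips the expression layer and plants distances
directly (base within/between distances plus uniform edge noise), giving
small instances whose optimum is provable by enumeration;
`random_weighted_graph` provides unstructured uniform-weight instances
for oracle-equivalence sweeps.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 200 random complete graphs
with n ∈ [3, 10] and weights uniform on [1, 10] for solver-vs-oracle
sweeps (the decision procedure is additionally checked at three thresholds
straddling each optimum); 1000 random triples for incremental-evaluation
consistency; 10 generator seeds of the default 60-sample expression
protocol for planted recovery; and the 12-vertex three-group distance
fixture (within 1, A–B = A–C = 10, B–C = 4) for hierarchy structure, where
every split is certified by enumeration. These sizes keep a full run at a
few minutes on a single CPU while leaving the memetic path (n > 15)
genuinely exercised by the 60- and 30-vertex recursion levels.

## Known limitations

- The memetic solver carries no optimality guarantee above the exact
  threshold; the shipped evidence is statistical (oracle agreement on
  small instances, planted recovery at desk scale).
- Exact enumeration is capped at n = 22 by design.
- `cut_tree` ordering relies on split values being comparable across
  disjoint subgraphs; with wildly heterogeneous subtree scales a
  different frontier policy (e.g. by cluster size) may be preferable.
- Newick split-value annotations are comments, not branch lengths; no
  branch-length estimation is attempted.
- No agglomerative mode, no similarity-matrix input (the objective is
  defined on distances; conversions are the caller's concern).
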