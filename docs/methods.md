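# Methods

This note documents the models and procedures implemented in `likertnet`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Item networks from ratings

An item's profile is its vector of responses across participants. The
association between two items is the cosine of the angle between those
vectors, which for non-negative Likert values lies in [0, 1] and reads as a
co-occurrence index: 1 for items that always co-occur, 0 for items that
never do. Two codings are supported:

- `raw` (default): the 1..L values are used as-is. This uses all the
  information in the ratings and requires no extra threshold choice.
- `binarized(threshold)`: responses are first recoded as endorsement
  indicators (rating ≥ threshold, default 4). This makes the similarity a
  strict co-occurrence probability at the cost of discarding gradation.

Published analyses of this kind do not always state which coding was used,
and the two can produce different filtered networks; both are exposed so
sensitivity to the choice can be checked. No centering is applied — the
measure is cosine, not Pearson — so shared positive means raise all
similarities. With 1–5 ratings the off-diagonal floor is substantial
(≈ `E[X]²/E[X²]` ≈ 0.82 for uniform marginals); the structure of interest
lives in the upper tail, which is exactly what the TMFG keeps. Items whose
vector is all zero (possible only under binarization) get similarity 0 to
everything, with a warning.

## TMFG filtering

The Triangulated Maximally Filtered Graph retains `3n − 6` edges forming a
maximal planar graph: a seed tetrahedron — the 4-clique with the largest
total pairwise weight, found by exhaustive (vectorized) search over all
4-subsets — followed by `n − 4` T2 moves, each inserting the node/face pair
with the maximal sum of the three new edge weights and splitting the used
triangular face into three. Planarity holds by construction (every move
subdivides a face of a planar triangulation) and is additionally verified
in tests with an independent planarity check.

Tie-breaking is pinned for determinism: equal insertion gains prefer the
lower node index, then the earlier-created face; equal seed-clique totals
prefer the lexicographically smallest 4-subset. After filtering, edges are
binarized to weight 1; all downstream measures treat the networks as
unweighted and undirected, so conditions are compared on graphs of
identical size and density.

## Macro measures and the node bootstrap

- CC: `c_i = 2 t_i / (k_i (k_i − 1))`, nodes with degree < 2 contribute 0;
  reported as the unweighted mean over all nodes.
- ASPL: mean BFS distance over reachable ordered pairs. Unreachable pairs
  are excluded rather than imputed, so the measure remains defined on
  disconnected subgraphs that arise under node subsampling.
- Q: `Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j)` maximized by
  Louvain (resolution γ = 1 by default), best of `n_restarts` seeded runs.

Because one network yields one value per measure, inference uses a
without-replacement bootstrap: each realization samples `n_nodes` items
(default ⌊n/2⌋ = 37 of 75) and computes CC/ASPL/Q on the partial network.
Two partial-network constructions are implemented:

- `tmfg` (default): re-run the TMFG on the sampled similarity submatrix.
  This preserves the `3n − 6` invariant, so realizations are always
  connected and the per-condition distributions compare graphs of equal
  density.
- `induced`: take the induced subgraph of the full 75-node TMFG. Sparser,
  occasionally disconnected; exposed because it is the other natural
  reading of "partial network", and reproduction attempts should try both.

Default 1000 realizations per condition. Within the bootstrap, Q uses a
single Louvain run per realization (the distribution over realizations
already integrates over optimizer noise; restarts are configurable).
Distributions are compared with a classical one-way ANOVA (η² =
SS_between/SS_total) and pairwise Student t-tests (pooled SD, two-sided,
Cohen's d), giving the conventional shapes F(2, 2997) and t(1998) at
3 × 1000 replicates. Welch tests are available by flag. A caveat
documented here deliberately: bootstrap replicates are subsamples of one
fixed dataset, not independent draws, so these p-values compare the
*bootstrap distributions*, not the underlying populations; the null
calibration test (two "conditions" sharing one similarity matrix) confirms
uniform p-values under that reading.

## Spectral comparison

A graph's density matrix is the combinatorial Laplacian rescaled to unit
trace: `ρ = (D − A) / ΣA`, where `ΣA` sums all adjacency entries (both
triangles), which makes `tr ρ = 1` exact. Von Neumann entropy is the
base-2 Shannon entropy of its eigenvalues with `0·log 0 = 0`. The distance
between two networks on the same labeled node set is
`sqrt( h(μ) − ½[h(ρ) + h(σ)] )` with `μ = (ρ + σ)/2` — the mixture is formed
on the matrices and then eigendecomposed (quantum JSD), not on the
spectra. The result is bounded in [0, 1]. Eigenvalues below −1e−10 raise;
tiny negative values from floating point are clipped to 0. Node sets must
match exactly; alignment is by sorted label, and mismatches raise rather
than silently reorder. No statistical test is attached to the distance —
it is a numeric comparison.

## Community detection

Louvain is implemented directly (dense-adjacency, two phases: greedy local
moves in seeded random node order until no move improves the modularity
criterion, then aggregation; repeated until the partition stabilizes) so
that per-phase modularity values are available — tests assert the phase
trace is non-decreasing — and so the bootstrap, the macro Q, and the meso
analysis all share one maximizer. Its solution quality is cross-checked
against networkx's independent Louvain in tests.

Consensus clustering: run Louvain `n_iter` times (default 1000), form the
co-assignment frequency matrix, zero entries below τ (default 0.5 — the
consensus literature uses values in 0.3–0.8 and results are insensitive in
that range for clear structure; configurable), re-cluster the thresholded
weighted agreement graph, and repeat until every off-diagonal entry is 0 or
1 (all runs agree), up to 50 rounds. Nodes isolated by thresholding keep
their single strongest agreement edge so the final partition covers every
node. The procedure is deterministic given the master seed and idempotent:
consensus of a consensus returns itself.

Partition agreement uses the unadjusted Rand index (fraction of node pairs
treated the same way by both partitions), matching the verbal definition
used in this literature; the adjusted-for-chance variant is provided as a
secondary output. Community × condition rating profiles take each item's
mean rating per condition as one observation, grouped by a reference
partition (by default the first condition's consensus partition), and are
tested with a type-II factorial ANOVA via statsmodels; with 3 conditions,
5 communities and 75 items per condition this yields the conventional
df (2, 210), (4, 210) and (8, 210).

## Core–periphery

The discrete two-block model scores a labeling by the Pearson correlation
between the off-diagonal adjacency and the ideal pattern `Δ_ij = 1` iff
either endpoint is core (core–periphery ties count as 1; the variant where
they count 0 exists in the literature — the objective here is pinned and
documented, and the optimizer only touches it through one function, so it
is swappable). Optimization is greedy best-improving single-node flips to
a local optimum, best of 100 seeded restarts; sufficient statistics
(periphery size, periphery-internal edges, per-node periphery degree)
update in O(degree) per flip. All-core/all-periphery labelings have zero
pattern variance and are excluded; a complete graph is returned all-core
with a degenerate flag, an empty graph raises. On graphs small enough for
exhaustive 2ⁿ search the greedy optimum matches the global optimum in
≥ 95% of random instances (tested). Worth noting: the optimum can be
counterintuitive — for a K4 with a pendant leaf on each clique node, the
best core is any 3 of the 4 clique nodes (corr 0.400), not the full clique
(0.389).

Cross-condition core structure is summarized by set arithmetic on the core
labels: the shared core (intersection across all conditions), per-condition
unique cores, and pairwise overlaps.

## Synthetic data generator

The generator emulates the target study design: by default 3 conditions
(labeled aesthetic / non_aesthetic / consumer) with 167/160/172
participants, 75 items in five planted blocks of 15, rated 1–5. The latent
model is multivariate Gaussian with block-constant correlations — ρ_w
within a block (default 0.5), ρ_b between (default 0.15) — sampled exactly
via shared factors (one global, one per block, plus idiosyncratic noise),
shifted by per-condition per-block latent means, and discretized at the
equal-probability normal quantiles Φ⁻¹(k/L). Construction validates
ρ_w > ρ_b (otherwise the planted structure is undetectable), positive
semi-definiteness of the implied correlation matrix, and non-empty blocks.
Default mean profiles place one block low (≈ −0.8 SD; the "negative"
cluster rated low everywhere) and give the first condition the strongest
endorsement of the positive blocks, mimicking high-endorsement rating
data. The default correlation strengths were chosen so that block structure
is clearly recoverable but not trivial — within-block cosine exceeds the
between-block floor by a few hundredths, comparable to what tail-filtered
rating networks show.

Condition effects act on block means only, by default. A `block_swaps`
option reassigns a chosen number of item pairs across blocks in one
condition's latent structure, creating genuine topology differences for
power studies. One master seed spawns per-condition substreams, so tables
are bit-identical across runs and adding a condition leaves the others
unchanged.

What the generator does *not* emulate: real response styles (acquiescence,
extreme responding), item-specific variances and skews, missingness,
cross-loading items, or any calibrated resemblance to a particular
published dataset's response distributions. Passing recovery tests on this
benchmark therefore demonstrates that the pipeline's inference machinery
works when its assumptions hold, not that any particular empirical network
is correctly estimated.

## Numerical and degenerate-input conventions

- TMFG requires n ≥ 4 and a symmetric matrix (tolerance 1e−8, then
  symmetrized by averaging); diagonal ignored.
- ASPL raises on edgeless graphs; bootstrap realizations record NaN if an
  induced subgraph loses all edges (cannot occur in `tmfg` mode).
- Zero-variance inputs to ANOVA/t-tests return a degenerate flag with NaN
  statistics instead of raising.
- Density-matrix eigenvalues are clipped at −1e−10; JSD negatives from
  rounding clip to 0 before the square root.
- All stochastic stages consume named substreams spawned from one master
  seed (recorded in the run manifest), so pipeline outputs are
  reproducible bit-for-bit.

## Problem sizes used in the test suite

The suite exercises the full 75-item design where the property depends on
it (TMFG edge counts, planted-block recovery with 1000-run consensus over
10 master seeds, 1000-realization bootstrap calibration over 20
repetitions, df shapes at 3 × 1000 replicates) and smaller sizes where the
property is size-free (exhaustive oracles up to 12 nodes for
core–periphery, 8 for CC/ASPL, partition pairs up to 7 nodes for the Rand
index). These sizes are the package's validation design: large enough to
be the stated study conditions, small enough that exhaustive oracles stay
exact.

## Known limitations

- Cosine on raw positive ratings conflates mean endorsement with
  co-variation; the binarized mode changes, not removes, that coupling.
  Reproductions of published numbers can differ by the coding choice alone.
- The unadjusted Rand index is generous when partitions have many small
  communities; the adjusted variant is reported alongside for that reason.
- Louvain (any implementation) is a heuristic; Q values carry optimizer
  noise of order 0.01 on 75-node TMFGs (tested), which the consensus and
  restart machinery, not the single run, is responsible for absorbing.
- The two-block core–periphery model forces a binary answer; gradations of
  coreness are out of scope by design.
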