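# Methods

## The problem

Given a collection of simple, undirected, unlabelled graphs, `netspect`
groups together graphs with *similar connectivity structure* — graphs
plausibly generated by the same random-graph model with the same
parameters — rather than clustering the vertices inside one graph.  The
motivating applications are functional brain networks (one graph per
time window of a multichannel recording) and molecular graph
collections, but nothing in the library is specific to either.

## Graph summary: the spectral density

A graph on `n` vertices is summarized by its adjacency spectrum
λ₁ ≥ … ≥ λₙ, smoothed into a density

    ρ_G(λ) = (1/n) Σⱼ K_h(λ − λⱼ),

with `K_h` a Gaussian kernel.  The bandwidth follows a fixed recipe:
`h = (λ₁ − λₙ) / b` where `b = ⌈1 + log₂ n⌉` is the Sturges bin count.
The density is evaluated on a shared uniform grid (default 512 points)
padded by `3h` beyond the extreme eigenvalues so the kernel tails are
captured, and renormalized so its trapezoid-rule area is exactly 1.
The spectral density is invariant under vertex relabeling, so no vertex
correspondence between graphs is needed, and it distinguishes
connectivity structures that share the number of vertices, the number
of edges, and even the full degree sequence.

Numerical choices worth knowing:

- The kernel-regression phrasing of the estimator is implemented as a
  kernel density estimate with the stated bandwidth; because the
  bandwidth and the final unit-area normalization are both fixed, the
  two coincide on the evaluation grid.
- A degenerate spectrum with zero spread (e.g. the empty graph) gets a
  fallback bandwidth of `max(|λ₁|, 1) × 1e−3` instead of dividing by
  zero.
- Densities that will be compared must share the identical grid;
  mismatched grids raise instead of silently interpolating.

## Divergences

KL and JS divergences are computed as Riemann sums on the shared grid.
Both densities are first converted to discrete probability masses
(density × trapezoid weight, renormalized), so the discretized KL is a
true discrete KL: it is nonnegative by the Gibbs inequality, zero iff
the discretized densities agree, and `+∞` exactly when the reference
density vanishes (below the 1e−300 underflow floor) somewhere the
target has mass.  Natural logarithms are used throughout, so
JS ≤ ln 2, and √JS satisfies the triangle inequality — the metric the
k-means uses.

## k-means for graphs (equal sizes)

Graphs of different sizes have different numbers of eigenvalues, and
their densities differ for that reason alone; the k-means therefore
refuses mixed-size input.  For equal-size graphs:

1. all densities are evaluated on one shared grid;
2. each restart assigns graphs to `K` clusters at random (degenerate
   initial assignments that leave a cluster empty are repaired by
   moving in the graph farthest from its own centroid);
3. each pass visits the graphs in a seed-controlled random order and
   greedily moves each graph to the centroid (arithmetic mean of
   member densities) with the smallest √JS distance, updating both
   affected centroids immediately; the outcome therefore depends on
   the visiting order, which is the intended greedy behavior;
4. a move that would leave a cluster empty is skipped, so every
   cluster stays populated and passes terminate;
5. the algorithm stops when a full pass moves nothing (or at
   `max_iter = 100` passes);
6. across `n_restarts = 10` restarts the result with the largest
   silhouette statistic (Rousseeuw's (b−a)/max(a,b), computed on the
   pairwise √JS matrix, singletons contributing 0) is returned.

The objective (sum of assigned √JS distances) is recorded per pass.
Because the centroid is the arithmetic mean of densities rather than
the JS Fréchet mean, monotone descent is not guaranteed in theory; in
practice the trace is non-increasing on separated data, and the
property is tested empirically, not proved.  One implementation detail
matters: centroids are maintained incrementally, and floating-point
cancellation can leave ~1e−20 *negative* mass dust after removals,
which the KL support check would misread as a violation — centroid
vectors are therefore clamped at zero before any divergence is
computed.

Ties in distance break toward the lowest cluster index.

## Parameter estimation and model selection

For a graph `G` assumed to come from model family `M`, the estimator is

    θ̂ = argmin_θ KL(ρ_G | ρ_M(θ)),

searched over a finite grid of candidate θ.  Since closed-form spectral
densities are unknown for most families, `ρ_M(θ)` is the Monte-Carlo
mean density of `n_mc = 50` independent draws (reduced in desk-scale
runs; see below), generated *at the same size as G*.  The KL grid spans
the target spectrum and every Monte-Carlo spectrum across all candidate
θ.  Model selection between families picks the family with the smallest
best-grid KL.

Default search grids, overridable per call: ER edge probability
0.01–0.99 step 0.01; geometric radius 0.05–0.95 step 0.05; k-regular
even degrees 2–min(n−1, 20); Watts–Strogatz rewiring probability 0–1
step 0.05 with the neighbor count fixed (a 2-D (k, p) grid is used when
it is not); preferential-attachment exponent 0.5–3 step 0.25 with the
edges-per-vertex fixed.

Monte-Carlo draws are seeded deterministically from the master seed
plus (model, θ, size, replicates), so results are reproducible and
independent of evaluation order, and they are cached under the same
key — the EM loop below re-evaluates the same model densities many
times, and without the cache it is infeasibly slow.

## gCEM (different sizes)

`gcem` is a classification-EM-style algorithm in which each cluster is
a random-graph model with parameter θ̂_k:

- **Initialization**: random partition into `K` groups, then one
  M-step.
- **E-step**: responsibility t_k(G_i) ∝ 1 / KL(ρ_{G_i} | ρ_{M_k}(θ̂_k)),
  with the model density generated at G_i's own size, normalized over
  clusters to sum to 1 per graph.  A zero KL concentrates the row on
  the zero-divergence clusters; infinite KL to *every* cluster falls
  back to a uniform row with a logged warning.
- **C-step**: assign each graph to its argmax responsibility (ties to
  the lowest index); a cluster left empty is repaired with the graph
  whose best responsibility is weakest.
- **M-step**: θ̂_k is the mean of the per-graph grid estimates of the
  cluster's members.  These per-graph estimates do not depend on the
  current θ̂, so they are computed once per (graph, model family) and
  the M-step reduces to averaging.  A mean θ̂ need not be a legal model
  parameter (e.g. a fractional degree), so it is projected into the
  model's domain (clipping, parity rounding) before any graph is
  generated from it.
- **Convergence**: relative change of Σᵢ t_{k(i)}(G_i) · KL_i below
  `tol = 1e−3`, or labels unchanged on two consecutive iterations,
  whichever first; hard cap `max_iter = 50`.

The responsibility normalization follows the "conditional probability
that a graph belongs to a cluster" reading: rows (per graph, over
clusters) sum to one.  The convergence quantity is aggregated by
summing over assigned graphs.

## Evaluation: simulations and the Jaccard index

Partitions are compared with the pair-counting Jaccard index
J = n11/(n11 + n10 + n01); this is the definition that puts the chance
level for the 10+10 two-cluster design at 45/140 ≈ 0.32 (derivable by
linearizing over pairs: a pair is co-clustered in the prediction with
probability ½ regardless of the truth, giving E n11 = 45·½, E n10 =
45·½, E n01 = 50·½ at large samples), matching the Monte-Carlo floor
the test suite measures.  The implementation delegates the pair counts
to scikit-learn's `pair_confusion_matrix`; an exhaustive
pair-enumeration oracle cross-checks it in the tests.

Three simulation families, each with known ground truth and
`run_scenario` defaults chosen as the study conditions:

- **sim1 (a–f)**: three clusters of 10 same-size graphs; scenarios a–e
  use one family with three parameter settings (ER p = 0.2/0.25/0.3;
  geometric r = 0.15/0.25/0.35; k-regular k = 2/4/6; Watts–Strogatz
  p = 0.05/0.10/0.15 at k = 16; preferential attachment ps = 1/2/3 at
  m = 10), scenario f mixes three families.  Clustered by k-means with
  K = 3.  Sizes 30–120 probe the size effect: spectral densities
  concentrate as n grows, so clustering improves with graph size.
- **sim2 (a, b)**: two clusters of 10 graphs at n = 100 with 1000
  edges each.  (a) Watts–Strogatz k = 20 with rewiring probability p
  swept 0–1 against ER G(n, m = 1000); (b) ring lattices (WS p = 0,
  k = 20) perturbed by 100–1000 degree-preserving double-edge swaps
  against random 20-regular graphs — size, edge count, *and* degree
  sequence all match, so only connectivity structure separates the
  clusters.  As the sweep progresses the clusters genuinely merge and
  any method must fall to chance.
- **sim3 (a–f)**: the sim1 scenarios with per-graph sizes uniform on
  [30, 120], clustered by gCEM with the generating family (or
  families, in f) as the model.

Repetition counts default to 20 in the runners (the published studies
use 100); confidence intervals are the normal approximation
mean ± 1.96·SE.

## Functional-network pipeline

`run_transition_pipeline` slices a channels × samples recording into
windows (window length and stride in samples), builds one graph per
window (edge iff within-window Pearson correlation strictly exceeds
the cutoff, default 0.5), clusters the graph sequence with k-means
(K = 2, all windows share the channel count), and maps clusters to
binary states by assuming the recording *starts* in state 1 (majority
vote over the first moving-average-window labels).  A transition is
the center of the first 50-label centered moving-average window whose
mean crosses 0.5 — downward for loss of the initial state, upward for
recovery.  Windows that do not fully fit are not evaluated (no
padding), so the earliest detectable center is at half a window.

### What the synthetic generator emulates — and what it does not

`synthetic_two_state_signals` drives every channel with one shared
latent standard-normal signal: `x_c(t) = c(t)·z(t) + σ·ε_c(t)`, where
the coupling `c(t)` switches between `coupling_high = 0.9` and
`coupling_low = 0.1` at the requested change points and `σ = 0.5`.
Expected pairwise correlation is `c²/(c² + σ²)` — about 0.76 in the
high state and 0.04 in the low state, so the thresholded graphs are
near-complete versus near-empty and the two states are separable at
cutoffs 0.45–0.55 alike.  This captures exactly one feature of real
recordings: a change point in the strength of shared fluctuation.  It
has no spatial structure, no oscillatory content, no slow drift, no
artifacts, and an instantaneous (not gradual) state change.  Passing
the end-to-end tests therefore demonstrates that the pipeline recovers
a coupling change point under idealized conditions; it says nothing
about preprocessing, electrode layout, or gradual anesthetic
transitions in real data.

Default test geometry: 16 channels, 200-sample non-overlapping
windows, 160 windows with the change at window 80, detection tolerance
half the 50-point moving-average window (±25).

## Problem sizes used in the checked runs

The test suite and the acceptance script scale the published designs
to desk size as the package's own validation conditions: 20
repetitions per sweep point for the Watts–Strogatz-vs-ER study, 10 per
rewire count for the rewiring study, 20 per size for the size-effect
comparison; gCEM recovery uses 10 runs with `n_mc = 20` and an ER grid
of 0.05–0.50 step 0.025; parameter-recovery unit tests use `n_mc` of
10–20 with shared Monte-Carlo caches.  Generator defaults themselves
(sizes, edge counts, model parameters, `n_mc = 50`, the 0.5
correlation cutoff, the 50-point moving average) are the study
conditions and are not scaled.

## Known limitations

- Spectral density computation is O(n³) per graph; gCEM additionally
  multiplies by the grid size and `n_mc`.  Collections of graphs with
  thousands of vertices are the practical ceiling.
- k-means requires equal vertex counts by design; use gCEM otherwise.
- The grid-search estimator cannot resolve θ below the grid step, and
  gCEM inherits that resolution.
- Small graphs (n below ~60) carry little spectral information and
  cluster noticeably worse — the size-effect tests quantify this.
- `K` is an input everywhere; the library does not choose the number
  of clusters.
- Eigenvector information is deliberately unused; only eigenvalues
  enter the summary.
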