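# Methods

This note records the models, numerical choices, and open design decisions
behind `clrnet`, and what its synthetic benchmark does and does not
establish.

## Association estimators

All seven estimators are symmetric functions of two expression profiles of
length m and are computed once per unordered gene pair. Degenerate inputs
follow one rule everywhere: a profile whose values are all equal carries no
association evidence, so every correlation-type score and MIC return 0
(never NaN), keeping downstream matrices finite.

* **Pearson / Spearman / Kendall.** Standard product-moment correlation;
  Spearman is Pearson on average ranks; Kendall is the tie-corrected τ-b
  (via scipy). All clipped to [−1, 1] against floating-point overshoot.
* **Theil–Sen association.** Theil–Sen proper is a robust *slope*
  estimator, not a correlation, so a bounded symmetric score is
  constructed: standardize both profiles (z-scores), take the median of
  all pairwise slopes of y on x (pairs with equal x excluded) and
  symmetrically of x on y, and combine as
  sign(β_yx)·min(1, √(β_yx·β_xy)), with 0 when the directional slopes
  disagree in sign. For an affine relation both standardized slopes are
  ±1 and the score is ±1. The O(m²) slope set is materialized and its
  median found by quickselect (exact, not sampled).
* **Weighted rank.** A weighted Pearson on the two rank vectors. The
  literature behind "weighted rank correlation" admits several weight
  schemes; here the default weight of observation k is
  ((m − r_x(k) + 1) + (m − r_y(k) + 1))/2 — linear top-emphasis averaged
  over the two rankings so the score is symmetric in its arguments — and
  the weight vector is an explicit parameter for anyone wanting a
  different scheme. With uniform weights it reduces exactly to Spearman.
* **Mutual information.** Plug-in estimator on an equal-width joint
  histogram over each profile's observed range, in bits; 0·log 0 := 0.
  Default resolution ⌈√m⌉ bins clamped to [2, 20] — a deterministic,
  standard bias/variance compromise (the classic B-spline CLR estimator
  is deliberately not reproduced; the estimator is treated as swappable).
* **MIC.** Maximal normalized grid information
  max I(a×b)/log2 min(a,b) over grid resolutions a·b ≤ B(m) = m^0.6,
  computed the usual way: one axis equipartitioned into b rows (runs of
  equal values never split), the other partitioned by dynamic programming
  over clump/superclump boundaries (clump cap c·a with c = 15), both
  orientations taken. Because B(m) < 4 leaves no admissible 2×2 grid for
  m ≤ 10, the budget is floored at B = max(m^0.6, 4). The DP optimizes
  exactly over column placements *given* the equipartitioned axis, so it
  can undershoot (never exceed) the enumerate-every-grid optimum; the test
  suite checks both the bound and exact agreement on structured data.

## CLR background correction and thresholding

For gene i, μᵢ and σᵢ are the mean and standard deviation (population
form, two-pass) of row i's off-diagonal association scores — the
background is every other gene, with no trimming. The rectified per-gene
z is uᵢ(j) = max(0, (Aᵢⱼ − μᵢ)/σᵢ) (uᵢ = 0 when σᵢ vanishes, including
σᵢ ≤ 10⁻¹² × scale to absorb cancellation in flat backgrounds), and the
pair score combines both directions in quadrature: zᵢⱼ = √(uᵢ(j)² + uⱼ(i)²).

Pair-level cutoffs are applied after a second standardization: the
off-diagonal CLR scores are centred and scaled by their own empirical
mean/sd, because at genome scale their distribution is close to normal
and cutoffs (e.g. 4.3 or 3.8) are naturally expressed as pair-level
z-scores. Negative standardized values are retained until thresholding;
ties at the cutoff are kept (≥). An all-equal input standardizes to all
zeros rather than erroring.

## Parallel execution contract

With n genes there are n(n−1)/2 unordered pairs. Row i of the score
matrix owns pairs {i, (i+d) mod n} for d = 1..⌊(n−1)/2⌋, plus the
antipodal pair {i, i+n/2} for i < n/2 when n is even: every pair has
exactly one owner and per-row loads differ by at most one. Rows are dealt
round-robin to workers. Workers only split rows — which pair is computed,
and by which formula, never depends on worker count — so inference output
is byte-identical for any number of workers. This is verified exhaustively
(all n ≤ 40, all p ≤ n) and end-to-end.

## Subnetwork extraction

Neither extraction heuristic has a published reference implementation to
match bit-for-bit; both are stated precisely here and frozen by tests.

* **Neighbourhood expansion** (SNBuilder-style): start from the seeds; in
  each round (default 2), candidates — non-members adjacent to the member
  set — are processed in lexicographic order and admitted when the overlap
  between their neighbour set N(c) and the member set M satisfies
  |N(c) ∩ M| / min(|N(c)|, |M|) ≥ inclusion_fraction (default 0.5), or
  when they touch ≥ 2 seeds. The min-denominator (an overlap coefficient)
  rather than |N(c)| alone is deliberate: it lets a single seed nucleate a
  dense module (a clique member adjacent to the seed overlaps it fully)
  while still rejecting bridge nodes whose neighbourhood lies mostly
  outside a grown member set. Admissions take effect immediately;
  processing order is fixed, so the result is deterministic.
* **Cohesive growth** (GeNa-style): greedily add the neighbour that most
  increases cohesion W_in/(W_in + W_out), where W_in is the total edge
  weight (standardized z) inside the member set and W_out the weight
  crossing its boundary; stop at a local optimum or max_size (default
  100). Ties break lexicographically. This produces small, tight modules —
  on the packaged fixtures never larger than the expansion heuristic's.

Seeds present in the network always survive into the output; edges are the
induced subgraph. Seeds absent from the network are reported; if none is
present, extraction is an error.

## Synthetic benchmark

The generator emulates a curated-seed expression simulator so the whole
pipeline is testable offline; it is not a bit-for-bit reproduction of any
published tool.

* **Topology.** Genes in fixed order; the first ~10% are sources. Each
  later gene takes 1–2 regulators among earlier genes chosen with
  probability ∝ out-degree + 1 (preferential attachment → heavy-tailed
  out-degrees, which the tests verify against an Erdős–Rényi control);
  ~30% of edges repress. Childless sources get a random target and any
  disconnected component is stitched on via a non-source member, so the
  skeleton is connected, acyclic, and every gene is reachable from a
  source. Per-edge kinetics are fixed at creation: K ~ U(0.2, 0.8),
  h ∈ {1, 2, 4}.
* **Subsampling.** Benchmark instances are connected k-gene (default 50)
  induced subgraphs grown by repeated uniform neighbour addition.
* **Expression.** Per sample, source activities ~ U(0.05, 1); each
  target's activity is the product of one Hill term per regulator
  (activation xʰ/(Kʰ+xʰ), repression Kʰ/(Kʰ+xʰ)) — an AND-like
  combination; richer regulator logic is out of scope. Measurement noise
  is two-stage: multiplicative lognormal biological noise (sd 0.1 by
  default on the log scale) on the activity, then additive Gaussian
  experimental noise (sd 0.1 by default) after log2 transformation. Noise
  does not propagate through the cascade (it models measurement, not
  intrinsic fluctuation — one acknowledged simplification versus real
  compendia). Cycles in user-supplied topologies are broken by dropping
  cycle-closing edges in insertion order, with a warning.
* **Design.** Group A compendia at 30–90 samples, Group B at 100–1000,
  AUC of the standardized CLR scores against the subnetwork's undirected
  skeleton (direction is not recoverable from symmetric association), per
  (group, size, method), averaged per group. Everything is deterministic
  given one integer seed. MIC is evaluated only at m ≤ 200 by default:
  its grid budget (and DP cost) grows steeply with m.

What a green benchmark test establishes: the pipeline recovers simulated
regulatory skeletons far above chance, and more samples help. What it does
not establish: estimator rankings on real microarray compendia — the
simulator's noiseless backbone is deterministic Hill kinetics, which
favours estimators sensitive to arbitrary (non-monotone) dependence. In
particular, with multi-regulator targets the binned MI and MIC estimators
dominate all four correlation families here, and in the noiseless limit
even indirect single-parent cascades are perfectly rank-coupled, capping
the AUC of every pairwise method well below 1. Measured on the packaged
benchmark (20 replicates, seed 0; Theil–Sen at 4 given its O(m²)-per-pair
cost): mutual information ≈ 0.90 and MIC ≈ 0.89 overall mean AUC versus
≈ 0.72 for Pearson/Spearman/Kendall/Theil–Sen/weighted-rank, which are
statistically indistinguishable from one another, while every method's
Group B (100–1000 samples) mean exceeds its Group A (30–90) mean.

## Evaluation

* **AUC** is the Mann–Whitney rank statistic with ties counted 0.5 —
  exactly the area under the full threshold-sweep ROC. Requires at least
  one scored positive and one scored negative pair.
* **Confusion metrics** follow the rescale-to-100 convention: (TP, FP)
  scaled to sum to 100, (TN, FN) likewise; then
  sensitivity = TP/(TP+FN)·100, specificity = TN/(TN+FP)·100,
  accuracy = (TP+TN)/(TP+FP+TN+FN)·100. Rescaling is idempotent; note it
  preserves the three metrics only when TP+FP = TN+FN already share a
  scale — in general it *changes* them (that is the point of adjusting
  the negative pool to the subnetwork's size). Display rounding is one
  decimal, half-up (68.55 → 68.6); unrounded values are kept internally.
* **Subnetwork evaluation** counts TP/FP over the subnetwork's genes and
  draws TN/FN from a uniform, seeded, same-size sample of the network's
  remaining genes, then rescales. The sampling seed is an explicit
  parameter; there is no hidden RNG state.

## Known limitations

* The simulator omits propagated intrinsic noise, multi-regulator logic
  beyond products, and self-/cyclic regulation; absolute AUC values are
  therefore properties of this stated world, not predictions for any
  external benchmark.
* MIC's DP is the standard approximation: exact given an equipartitioned
  axis, a lower bound otherwise.
* The MI estimator's equal-width binning is sensitive to extreme outliers
  (all mass in few bins); profiles are used as-is, with no winsorizing.
* Edge direction and sign are not inferred; all networks are undirected
  and unsigned past the simulator.
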