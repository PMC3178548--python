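# Methods

## Model

A peak is an observation x = (m/z, RT) with a charge z. Peak matching is
cast as robust location estimation under a hard, position-specific
variance constraint: all members of a cluster must lie inside the closed
box center ± (δ₁, δ₂), where δ₁ = ppm · 10⁻⁶ · (m/z) and δ₂ is an
absolute RT half-width. The cluster center is an M-estimator of location:
the minimizer of a robust objective of standardized residuals
r = (x − μ)/σ, computed as an iteratively reweighted mean with weights

    w(r; c, T) = exp(−r²/2T) / (exp(−r²/2T) + exp(−c²/2T)).

Properties used by the algorithm:

* w(c) = ½ for every T (exactly, by construction);
* T → ∞ gives w ≡ ½, an ordinary mean;
* T → 0 gives the indicator of |r| < c — the skipped mean;
* the influence ψ(r) = r·w(r) redescends to 0, so remote peaks are
  effectively discarded rather than merely down-weighted.

Setting σᵢ = δᵢ/3 and c = 3 places the half-weight point on the box edge
in each coordinate; coordinate weights are multiplied. Redescending
estimators have local minima; deterministic annealing (starting the
iteration at high T, where the objective is smooth, and cooling) removes
the dependence on the starting point.

Numerically the weight is evaluated as the logistic sigmoid of
(c² − r²)/(2T), which is exact, monotone, and cannot overflow; far beyond
the cutoff at low temperature it underflows gracefully to 0 (never NaN).

## Clustering loop

Peaks are processed independently per charge. For each unused seed (input
row order by default; descending intensity optionally):

1. Frame: all unused same-charge peaks within ±3δᵢ of the center (closed
   intervals; δ₁ evaluated at the current center's m/z and re-evaluated
   whenever the center moves).
2. At each schedule temperature T_k (default 8, 6, 4, 3, 2, 1.5, five
   steps at 1, final 0.25): weight the frame peaks, move the center to the
   weighted mean, recompute the frame.
3. Early stop (a): if every frame peak with weight > w₀ = 0.1 is already
   inside the box around the current center, jump to the final pass.
   Early stop (b): if the center moved by ≤ 0.1% of δᵢ in both
   coordinates, likewise.
4. Final pass (the last schedule temperature): the weight function at
   T = 0.25 is, to working precision away from the edge, a cut at the box
   boundary, and it is implemented as exactly that — the center becomes
   the arithmetic mean of the in-box frame peaks (skipped mean) and the
   membership is the closed box around that final center. This makes the
   final membership exact and deterministic instead of depending on a
   weight threshold, and it is what makes the skipped-mean identity
   testable to 1e-9.

Members are marked used and the next seed is taken. A seed can end up
outside its own grown cluster when the center migrates to a denser
neighbourhood; it then simply seeds again later (degenerate cases fall
back to a seed singleton, so every peak is assigned exactly once and the
run is deterministic). The iteration count per cluster is at most the
schedule length (12); isolated, tolerance-respecting clusters finish in
one iteration via rule (a).

## Post-processing

Two clusters overlap when their closed boxes intersect (same charge only;
each box's δ₁ at its own center). The transitive closure partitions
clusters into overlap components.

**Stage 1 — global reassignment.** Within each multi-cluster component,
iterate at T = 1: assign every component peak to the cluster of largest
combined weight (ties → lowest cluster id), recompute centers as
per-coordinate mid-ranges, until the assignment is stable (cap 100
iterations — largest-weight reassignment with mid-range recentering is
not provably convergent, and a cap turns a potential oscillation into a
deterministic stop). Mid-range centering contains all members iff the
per-coordinate spread ≤ 2δ; since largest-weight assignment can violate
that, any out-of-box peak is split into a fresh singleton cluster after
convergence. The tolerance contract therefore holds unconditionally.
Single-cluster components pass through untouched.

**Stage 2 — fusion.** Visit clusters in ascending id; among overlapping
neighbours pick the one whose center has the largest weight at T = 1
relative to the visited cluster's center (standardized with δ₁ at the
visited cluster's m/z); fuse if the union's spread fits one box, with δ₁
evaluated at the fused mid-range m/z. Passes repeat until none fuses
(single-pass mode available); repeating is order-insensitive at the
fixpoint and leaves already-stable results unchanged. An already-fused
(used) cluster remains a legal fusion *partner* within the same pass,
matching the greedy description of the procedure.

Both stages conserve the peak multiset, preserve the box invariant, and
are idempotent on their own output — all asserted by tests.

## Synthetic data

The generator emulates a concatenated, run-to-run-corrected multi-sample
peak list: `n_peptides` true locations uniform over the m/z and RT
ranges, one charge each (default mix 1:2:3 = 0.15:0.55:0.30, roughly
tryptic), `n_samples` replicate peaks per peptide minus Bernoulli
dropout, m/z scatter proportional to location (ppm-scaled) and
constant-scale RT scatter, plus uniform background peaks labelled
`noise`. `overlap_pairs` adds companions 1–2 full box widths from their
partner (adversarial for the annealing); `long_elution` spreads one
peptide over more than a box width of RT, the legitimate multi-cluster
case.

Defaults are a 12-replicate study against the box δ₁ = 2.93 ppm,
δ₂ = 0.3 min, with within-cluster scatter of δ/6 per coordinate
(0.5 ppm, 0.05 min), truncated at ±3 sd. The truncation bounds each
cluster's extent to ±δ/2 around its true location, so every synthetic
cluster respects the tolerance box *by construction* no matter which
member seeds it — the regime in which exact recovery (ARI = 1) and
single-iteration convergence are the correct expectations, and the
regime the tolerance-setting procedure targets in practice (tolerances
are chosen wide relative to observed landmark variation). With scatter
at the box scale itself (sd ≈ δ/3 untruncated), peaks can fall outside
any box containing their siblings and exact recovery is no longer
attainable by *any* constraint-respecting matcher; tests covering that
regime therefore assert the constraints, not label recovery.
`min_separation` (default 8 half-widths, required in at least one
coordinate) keeps independent peptides out of each other's search
frames; rejection sampling enforces it.

What passing synthetic tests do **not** show about real data: real peak
lists have drift and correlation structure that run-to-run correction
only partially removes, heavy-tailed RT errors, charge-assignment
errors, and peptides that genuinely elute at multiple times — so real
clusters-per-peptide means exceed 1 even for a perfect matcher.

## Numerical and design choices

* All box and frame tests use closed intervals: a peak exactly at
  tolerance respects the tolerance.
* Ties in largest weight (both stages) go to the lowest cluster id;
  seeds are taken in input order — determinism everywhere, byte-identical
  reruns.
* The weight's two printed forms disagree if the φ-notation is read as a
  standard normal density of r/T; the explicit exponential form (with
  r²/2T in the exponent) is implemented, as it alone satisfies the
  w(c) = ½ identity and both temperature limits.
* Dispersion uses the population convention (sd of n values with divisor
  n), so single-peak peptides contribute 0 and are subsequently removed
  as ties in ratio comparisons. One-zero ratio pairs (one algorithm at
  zero dispersion) are tallied separately rather than mapped to 0 or ∞.
* Cluster "diameter" is the per-coordinate range (max − min), the
  natural companion of the 2δ box width.
* Problem sizes in the test suite (up to ~50,000 peaks, 200 replicate
  frames, 50-cluster closure oracles) are chosen so the full suite runs
  in well under a minute while still exercising every code path at
  realistic density.

## Limitations

* Tolerances are user inputs; calibrating them from landmark peptides is
  upstream of this package, as are feature detection, charge assignment
  and m/z–RT correction.
* Stage 1 is a heuristic fixed-point search, not a globally optimal
  assignment solver; the iteration cap guarantees termination, not
  optimality.
* Charges are taken as given (z = 0 allowed as "unknown", processed as
  its own group); no charge inference or cross-charge matching.
* No raw-spectrum, isotope-envelope or chromatographic-peak-shape
  simulation: the generator starts where feature detection ends.
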