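# medea-lcms

Variance-constrained clustering for label-free LC-MS peak matching.

## The problem

Label-free proteomic and metabolomic experiments detect thousands of
features per LC-MS run, each parameterized by mass-to-charge ratio (m/z),
retention time (RT) and charge (z). Comparing abundances across samples
requires *peak matching*: grouping the features that represent the same
peptide across all runs. Two physical facts constrain the grouping — a
valid group must fit inside a tolerance box whose m/z half-width δ₁ is
*relative* (a few parts per million, so it grows with the m/z position)
and whose RT half-width δ₂ is absolute (minutes); and features of
different charge can never be the same ion. Generic clustering algorithms
cannot enforce such position-specific variance constraints; this package
implements MEDEA (M-Estimator with DEterministic Annealing), which builds
the constraint into the estimator itself.

## The method

Each cluster center is a robust location estimate computed by iteratively
reweighted means with the redescending weight

    w(r; c, T) = exp(−r²/2T) / (exp(−r²/2T) + exp(−c²/2T)),

where r = (x − μ)/σ is the standardized residual, T the annealing
temperature, and c the cutoff. Setting σᵢ = δᵢ/3 per coordinate and c = 3
puts the half-weight point w = 0.5 exactly on the box edge; per-coordinate
weights are multiplied. As T → ∞ the weights flatten to ½ (an ordinary
mean); as T → 0 they become the indicator of the box, making the estimator
a *skipped mean* that ignores everything outside the tolerance.

Clustering proceeds per charge state: an unused peak seeds a center, peaks
within ±3δᵢ are weighted against it, the center moves to the weighted mean,
and the temperature falls along the schedule 8, 6, 4, 3, 2, 1.5, 1 (×5),
0.25, with early termination when the cluster is already coherent (the
common case: isolated clusters finish in one iteration). Two
post-processing stages repair the greedy sequential pass: overlapping
clusters exchange peaks by largest weight with mid-range recentering
(stage 1), and clusters whose union fits a single box are fused (stage 2).
Every output cluster satisfies the closed-box constraint and charge purity.

Validation statistics mirror standard practice: per-peptide dispersion
σ_P (the standard deviation of assigned-cluster mean locations over a
peptide's peaks; 0 for a perfectly matched peptide), dispersion ratios
between two algorithms with ties removed (ε = 0.05), clusters-per-peptide
histograms, and cluster summary tables.

## Worked example

```python
from medea import MedeaPeakMatcher
from medea.simulate import SyntheticConfig, generate

peaks = generate(SyntheticConfig(n_peptides=25, n_noise=40,
                                 overlap_pairs=3, rng_seed=7))
results = MedeaPeakMatcher.from_dataframe(peaks, mz_ppm=2.93,
                                          rt_halfwidth=0.3).fit()
print(results.summary())
print(results.recovery())
```

prints

```
MEDEA peak matching results
==============================================
Peaks                         339
Tolerance half-widths         2.93 ppm (m/z), 0.3 min (RT)
Annealing schedule            12 steps, T1=8.0, Tfinal=0.25
Stages run                    stage1=True, stage2=True
----------------------------------------------
Number of clusters            68
Average cluster size          4.985
Average cluster diameter m/z  0.0006329
Average cluster diameter RT   0.06488
Box-constraint violations     0
Clusters per charge           z=1: 9, z=2: 42, z=3: 17
Annealing iterations          1: 68
Stage-1 peaks reassigned      0
Stage-2 clusters fused        0

ARI 1.0000 over 28 peptides (40 noise peaks excluded); clusters/peptide mean 1.000 [1:28]
```

339 synthetic peaks (25 isolated peptides, 3 deliberately adjacent
companions, 40 background peaks) collapse into 68 clusters — one per true
peptide plus singleton noise. Every cluster fits its tolerance box
(violations 0), all seeds resolved in a single annealing iteration because
the clusters are isolated, and the adjusted Rand index against the known
labels is exactly 1.

The same pipeline is available from the shell:

```
medea simulate --out peaks.tsv --seed 7 --peptides 25 --noise 40
medea cluster --in peaks.tsv --out out/ --ppm 2.93 --rt-tol 0.3
medea evaluate --clusters out/assignments.tsv --truth peaks.tsv
```

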