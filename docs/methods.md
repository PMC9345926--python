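# Methods

This note documents the statistical procedures implemented in `sbbrep`,
the parameter defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical decisions a
user auditing results should know about.

## Study design

One cohort of n subjects (reference shape: n = 420, ages 22–37, half
female, education as a third confounder, 34 behavioural scores) is
repeatedly partitioned into a discovery sample and a test sample at three
ratios (70/30, 50/50, 30/70; discovery sizes 294/210/126 at n = 420),
with `n_splits = 100` partitions per ratio. Every (score, ratio, split)
triple is one exploratory analysis; the default design therefore runs
34 × 3 × 100 = 10,200 of them.

**Matched splitting.** Subjects are stratified jointly on gender and age
quintile. The discovery sample is drawn without replacement with
per-stratum counts fixed by largest-remainder apportionment, hierarchically:
gender totals first, then age bins within gender. This makes gender counts
exact whenever `ratio × count(gender)` is an integer, and the complement —
which is the test sample — automatically mirrors the same strata mix, which
is how the "age- and gender-matched test sample" contract is realized when
the test sample is the full remainder. A stratum that cannot supply its
target raises a matching failure naming the stratum. Homogeneity of each
score across the splits' discovery samples is reported via one-way ANOVA
(means) and Brown–Forsythe/Levene with median centring (variances); these
are diagnostics only and never trigger redrawing. Education balance is
reported in the per-split audit but not matched on.

## Exploratory inference

**GLM.** At each vertex, ordinary least squares of thickness on
`[1, score, confounders]`; the reported statistic is the t-value of the
score coefficient with df = n − p. Confounders are age, gender and
education, except that the tested variable is never included as its own
confounder (relevant when age is the score of interest). Zero-variance
vertices get t = 0 with a warning; exact fits get an ±inf sentinel.

**TFCE.** `TFCE(v) = Σ_h e_h(v)^E · h^H · dh` over a ladder of
thresholds applied to the tail-rectified t-map, where `e_h(v)` is the
vertex count of the suprathreshold component containing v. Defaults
E = 1, H = 2 (the standard surface choice); the ladder step is adaptive,
`dh = max|t| / n_steps` with `n_steps = 100`, shared by both tails and both
hemispheres of one map. Cluster extent is vertex count, not surface area
(a `size_measure` hook is left on `ClusterSet` for an area-weighted
variant). The implementation walks the ladder top-down with a weighted
union-find over the mesh graph (numba-compiled, exact NumPy fallback);
it is validated against a brute-force per-threshold component-labelling
oracle over all 3-level maps of a 3×3 lattice and on random maps.

**Permutation FWE.** Freedman–Lane: thickness is residualized on the
confounders plus intercept, residual rows are permuted (one subject
permutation shared by both hemispheres), the full model is refit, and the
null distribution collects the per-permutation maximum TFCE over both
tails, all hemispheres and all vertices. This joint max-statistic is a
conservative, well-defined way to correct simultaneously for the two-sided
test and the two hemispheres. The corrected p-value is
`(1 + #{null max ≥ TFCE_obs(v)}) / (n_perm + 1)` (never zero); the default
is 1000 permutations, α = 0.05. When `n_perm ≥ n!` the permutation group
is enumerated exhaustively (identity included) and `p = count / n!`.
Calibration: on 100 pure-null synthetic datasets (n = 60, 484-vertex
lattice, 500 permutations) the empirical family-wise error rate lies
within the binomial 95% interval around the nominal 0.05 (recomputed by
`scripts/acceptance.py` and the test suite).

**Clusters.** Significant vertices (corrected p < α) are decomposed into
connected components separately per t-sign and hemisphere, sorted by size.

## Consistency aggregation

Per-split significance masks are summed into an overlap map (count per
vertex, 0..n_splits). Density summaries describe the distribution of
overlap frequencies, as percentages of n_splits, over the support of
ever-significant vertices only — vertices never significant are excluded,
matching the interpretation of the consistency maps. The headline summary
is the median frequency; it declines as the discovery sample shrinks.

## Confirmatory replication

For each discovery cluster (ROI), mean thickness over the ROI's vertices
is computed per subject in both samples. The association with the score is
a **ranked partial correlation**: rank-transform the ROI mean and the
score (average ranks for ties), residualize both on the confounders plus
intercept, Pearson-correlate the residuals; two-sided p from
`t = ρ√((n−2−k)/(1−ρ²))` on n−2−k df. Criteria:

- **sign**: sign(r_discovery) = sign(r_test); an exactly-zero correlation
  counts as a mismatch (conservative).
- **significance**: sign agreement *and* `p_test < α / k`, where k is the
  number of significant clusters from the paired discovery analysis of the
  same score (the per-split Bonferroni denominator). A two-sided p with an
  explicit direction check is used rather than a one-sided p — the more
  conservative composite.
- **Bayes factor**: two-sided BF₁₀ for the test-sample correlation under a
  stretched-beta(1/κ) prior on ρ (default κ = 1, i.e. uniform on (−1,1)),
  computed by numerical integration of Hotelling's exact sampling density
  of r; a one-sided variant is available (`side="one-sided"`). With κ = 1
  this coincides with the Jeffreys default correlation BF (it matches
  pingouin's implementation to ~1e-13, which the tests exploit as an
  independent oracle). Categories: BF ≥ 3 strong-H1 (boundary inclusive),
  [1,3) anecdotal-H1, (⅓,1) anecdotal-H0, ≤ ⅓ strong-H0. The BF is
  evaluated at the rank-residual correlation with n = n_test; the
  confounder adjustment is not propagated into the effective sample size,
  a deliberate simplification at k = 3 confounders.

Percentages of replicated ROIs are pooled over all clusters from all
splits, per score × ratio × criterion.

## Power analytics

Replication power treats the discovery effect size as true:
`power = Φ(√(n_test − 3)·atanh|r_discovery| − z₁₋α)` with α = 0.05
one-sided, the Fisher-z approximation of the conventional correlation
power computation (a Monte-Carlo simulation of the test cross-checks it in
the suite; e.g. r = 0.3, n = 100 gives 0.920). `n_test` is used — power
*of replication* refers to the sample doing the replicating. Power is
compared between replicated and non-replicated ROIs with a self-contained
two-sided Mann–Whitney U: exact enumeration of all group assignments when
both groups have ≤ 8 members (tie-safe), otherwise the normal
approximation with tie correction and no continuity correction. Effect-size
scatter (r_test vs r_discovery) gets per-group OLS lines; under selection
on discovery significance, discovery magnitudes systematically exceed test
magnitudes (winner's curse), which the suite verifies on null data.

## Synthetic cohorts

The generator is a pure function of (configuration, seed) and emulates the
statistical shape of the study, not cortical anatomy:

- **Demographics**: ages truncated-normal (28 ± 3.7, clipped to 22–37);
  gender drawn to the configured balance exactly after rounding; education
  normal (15 ± 1.8 years, clipped 8–24).
- **Scores**: 34 i.i.d. standard-normal scores by default (uniform and
  per-score MCAR missingness configurable); 31 are pure null, 3 carry
  planted effects.
- **Thickness**: baseline 2.5 mm plus planted effects plus noise. Noise is
  white Gaussian, graph-smoothed by 3 iterations of neighbour averaging
  (self-weight 0.5) for spatial autocorrelation, then rescaled per vertex
  so its realized between-subject SD is exactly `noise_sd` (default
  0.15 mm). Baseline, SD and smoothing are synthetic conventions of
  plausible magnitude, not fitted to any dataset.
- **Planted effects** live on connected vertex patches and are specified
  either as a slope (mm per unit) or a target correlation r, converted via
  `slope = r·σ_noise/(σ_target·√(1−r²))`. Effects **taper** linearly with
  graph distance from a core vertex (default panel: age effect core
  r = −0.45 tapering to 15% at the patch edge; three score effects at
  r = 0.25 tapering to 40%). The taper is essential realism: a spatially
  uniform effect is either detected everywhere or nowhere, saturating the
  consistency maps at 100%, whereas a tapered core reproduces the graded
  overlap distributions and their decline with sample size that the
  pipeline is meant to measure.
- **Meshes**: two icosphere hemispheres (resolution 2, 162 vertices each,
  by default) stand in for the registered fsaverage surface; all algorithms
  are resolution-agnostic.

What passing tests on this panel show: the pipeline's error control,
seed-reproducibility, and qualitative behaviour (detection and overlap
rising with sample size and effect strength, null scores controlled at the
nominal FWE level, winner's-curse shrinkage). What they do not show:
quantitative replication percentages for real cortical data, whose
spatial covariance, effect topography and score distributions differ from
these conventions.

## Numerical and engineering decisions

- Vertex indices are 0-based internally; 1-based edge-list dialects are
  converted at the I/O boundary. Hemispheres never share adjacency.
- Gaussian surface smoothing is approximated by iterated weighted
  neighbour averaging; geodesic-kernel smoothing is out of scope.
- `round(ratio·n)` is half-away-from-zero; the reference sizes
  294/210/126 are exact products, so no ambiguity arises there.
- TFCE threshold comparisons use `value ≥ h − 1e-12`; the union-find and
  oracle implementations share this rule, so they agree exactly.
- Seeds: one master seed; every task derives its own seed as
  `sha256(master | role | score | ratio | split)` reduced below 2³¹, so
  task results are independent of execution order and safely
  parallelizable; reruns are resumable via per-task JSON records (a
  present record is trusted and skipped).
- Degenerate inputs are errors, not silent results: constant scores
  (homogeneity), constant correlation inputs, empty ROIs, rank-deficient
  designs, disconnected effect patches, exhausted matching strata.
- Scale of the calibration runs in the test-suite and acceptance script
  (100 null datasets × 500 permutations; 20 splits × 3 ratios × 250
  permutations for the planted-effect trend): chosen as the smallest sizes
  at which the binomial intervals and the monotone trend are informative.

## Known limitations

- Family structure (related individuals) is not modelled; permutations
  assume exchangeable subjects.
- Cluster extent is vertex count, not surface area.
- The BF's effective sample size ignores the confounder count (see above).
- The matched split draws the test sample as the full complement; designs
  where the test sample is a proper matched subset of the remainder would
  need an additional subsetting step in `make_splits`.
- On a 12-subject balanced cohort at ratio 0.5, exactly equal gender
  counts across the halves require even per-gender counts; with odd
  counts the halves differ by one (apportionment remainder) — unavoidable
  integer arithmetic.
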