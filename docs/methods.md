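# Methods

This note documents the statistical procedures implemented in `splinegan`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Spline regression for a two-group time course

Expression of each gene is modeled as a natural cubic spline in time,
shared structure for both groups plus a differential block switched on by
the group indicator x:

y(t, x) = b0 + Σ bj Bj(t − t0) + x · (d0 + Σ dj Bj(t − t0)).

- **df (default 3).** Number of spline basis functions m. Low df keeps the
  per-gene model identifiable with ~14 observations per group and smooths
  over measurement noise; df is a parameter of every entry point.
- **Knots.** Boundary knots at the min/max of the pooled sampling times;
  df − 1 interior knots at the k/df quantiles (k = 1..df−1) of the pooled
  time vector, replicates included, using linear interpolation between
  order statistics (the type-7 convention, h = (n−1)p + 1). The quantile
  estimator and whether replicates are pooled are not dictated by the
  model itself; with a balanced design ties make both choices coincide,
  and pooled-with-replicates is used because it weights the knot positions
  by the actual sampling effort. An interior knot colliding with a
  boundary knot raises an identifiability error rather than being
  perturbed silently.
- **Basis.** The truncated-power natural basis: columns
  [s, d_1 − d_{K−2}, ...] with d_k(s) = [(s−ξk)₊³ − (s−ξK)₊³]/(ξK − ξk)
  on the shifted axis s = t − t0. It is piecewise cubic, C² at every knot,
  and exactly linear outside the boundary knots. Only the column *span*
  matters downstream: the moderated F is invariant under any
  reparameterization of the basis (verified in the tests against an
  independent B-spline construction with natural boundary constraints).
- **Design.** Columns [1, B1..Bm, x, x·B1..x·Bm]; the differential block
  is always the last m + 1 columns. Each group must observe at least
  df + 1 distinct times, otherwise the model is not identifiable and the
  fit refuses to run.

Technical replicates are treated as independent rows; no replicate random
effect is included (the moderated test's pooling absorbs the modest extra
technical variance, and the null simulations confirm the type-I error is
controlled without it).

## Moderated F test

Per-gene OLS gives coefficients, residual variance s²_g with d_g = n −
2(m+1) df, and the design-level unscaled covariance C of the differential
block. The hierarchical model s²_g | σ²_g ~ σ²_g χ²_{d_g}/d_g,
1/σ²_g ~ χ²_{d0}/(d0 s0²) is fitted by matching the first two moments of
log s²_g (digamma/trigamma equations; the trigamma inverse is solved by
Newton iteration to 1e-8). Numerical/degenerate choices:

- If the observed spread of log-variances does not exceed the sampling
  noise implied by d_g, the prior df is infinite and every gene's
  posterior variance equals the pooled value; in this branch the pooled
  value is the geometric mean of the sample variances, which keeps the
  fully degenerate case (all variances identical) fixed at that common
  value.
- Genes with s²_g = 0 (exact fits) cannot enter the log-moment equations;
  they are excluded from hyperparameter estimation with a logged warning
  and still receive a strictly positive posterior variance through the
  prior.
- The F statistic is d̂'C⁻¹d̂ / ((m+1) s̃²_g) with null F(m+1, d0 + d_g);
  for d0 = ∞ the limit χ²_{m+1}/(m+1) is used. With d0 forced to 0 this
  is exactly the classical full-vs-reduced-model block F (tested to
  1e-8).

Multiple testing uses Benjamini–Hochberg; selection is strict
(adjusted p < threshold, default 0.05).

## Shrinkage dynamic partial correlation

- **Dynamic weights.** Observation at distinct time t_i gets weight
  proportional to (t_{i+1} − t_{i−1})/2 with half-intervals at the ends;
  replicates at a time split its weight. This makes densely sampled early
  phases count by their share of the time axis rather than their sample
  count. With equally spaced times and balanced replicates the weights
  are uniform and the whole estimator reduces to the classic static
  shrinkage estimator (tested).
- **Shrinkage.** The weighted correlation matrix R is shrunk off-diagonal
  by λ* = clamp[0,1]( Σ Var̂(r_ij) / Σ r²_ij ). Var̂(r) is the weighted
  generalization of the unbiased variance-of-correlation estimate:
  Var̂(r) = h1² · (Σw²) · Var̂_unb(u) with u the products of standardized
  residuals, h1 = 1/(1 − Σw²), which reduces to the familiar
  n/(n−1)³ Σ(u−ū)² for uniform weights. λ* > 0 guarantees positive
  definiteness for p ≫ n; the effective sample size is n_eff = 1/Σw².
- **Partial correlations.** P_ij = −Ω_ij/√(Ω_ii Ω_jj), Ω = (R*)⁻¹,
  diagonal set to 1 and entries clipped to [−1, 1] against rounding.

## Posterior edge probabilities

The observed partial correlations are modeled as a two-component mixture
η0 f0(r; κ) + (1 − η0) fA(r), f0(r; κ) = (1−r²)^{(κ−3)/2}/B(½, (κ−1)/2).

- κ is the null concentration parameter, fitted by maximum likelihood on
  the central pairs (|r| up to its 90th percentile). The search runs on a
  log scale essentially unbounded above (up to 1e8): after strong
  shrinkage the partial correlations concentrate far below the raw
  1/√n_eff scale, so κ routinely needs to be much larger than any
  multiple of n_eff; capping it would make the null too wide and suppress
  all edges. A fit pressed against κ ≤ 3 (data more dispersed than any
  valid null) raises an error asking for more observations.
- η0 is the tail-ratio estimate at r0 = median |r|: empirical mass of
  {|r| ≤ r0} over the null mass, clamped to (0, 1].
- The marginal density f is a Gaussian kernel estimate (Silverman
  bandwidth) reflected at ±1 so no mass leaks outside the support.
- prob = 1 − min(1, η0 f0(r)/f̂(r)); wherever the estimated local fdr
  exceeds 1 the probability is clamped to 0. If every r is numerically
  zero all probabilities are 0.

Edges require prob ≥ 0.95 (inclusive); genes left without a retained edge
are dropped from the network, so "nodes" counts only connected genes.
By default only treatment-group observations feed the estimator
(replicates concatenated as independent longitudinal series); `all` pools
both groups. Density uses the ordered-pair denominator
n_edges/(n·(n−1)).

## Hubs, enrichment, evaluation

- Centralities on the unweighted graph: degree; betweenness
  (unnormalized, endpoints excluded — ranks are insensitive to the
  normalization constant); closeness per connected component,
  (n_c − 1)/Σd (harmonic closeness available behind a flag). Each measure
  is ranked with ties averaged; the combined measure is the mean rank;
  final ties break by gene symbol so hub lists are reproducible. The hub
  count is fraction·N rounded half away from zero (default fraction
  0.05).
- Enrichment: one-sided Fisher exact test per gene set (hypergeometric
  upper tail), sets intersected with the universe first; the default
  universe is the measured (tested) genes, which is the statistically
  defensible choice when the collection covers more genes than the assay.
  BH-FDR across tested sets, ranked ascending.
- Evaluation: both networks restricted to common nodes; observed shared
  edge count compared with n = 1000 uniform node-label permutations of
  the reconstructed subnetwork (topology preserved exactly). p =
  #{count ≥ observed}/n — ties count against significance, and the plain
  n denominator matches the granularity of permutation p-values such as
  0.048 at n = 1000 (an add-one estimator is available behind a flag).
  Significance is declared at p < 0.1.

## Synthetic data

The generators emulate the study design the pipeline assumes: two groups,
times 0.25–24 h (7 points), 2 replicates per group per time, log2-scale
intensities around 7 ± 1.

- Baseline profiles are random curves in the *fitted model's own span*
  (random coefficients on intercept-orthogonalized, variance-standardized
  natural-spline columns), so null simulations carry no approximation
  bias: any rejected gene is a genuine false positive. Gene noise
  variances follow the scaled inverse-χ² prior with d0 = 4, s0² = 0.05 —
  plausible values for log2 microarray data and the same hierarchy the
  moderated test assumes.
- Differential genes add a treatment-only profile (constant offset +
  spline curve) of total size effect_size in units of the gene's noise
  SD; effect_size 3 with 5% differential genes gives sensitivity above
  0.8 at FDR 0.05 in the tests.
- The conditional-dependence generator plants a precision matrix
  Ω = I + s·A with A the adjacency of disjoint cliques (greedy K4/K3/K2
  partition of the edge budget), giving *exact* planted partial
  correlations of magnitude s (sign negative, a mutual-inhibition
  pattern) and positive definiteness for any s < 1. A uniform-magnitude
  random graph is spectrally infeasible at the benchmark setting (40
  edges on 30 nodes at s = 0.4 would need λmax(A) < 2.5 while the mean
  degree alone forces λmax ≥ 2.67), which is why the clique construction
  is used. Independent per-gene smooth trends of SD 0.1 (noise-SD units)
  are superimposed; the amplitude is kept small because shared-axis
  trends contaminate the marginal covariance and would distort the
  planted partial correlations that define the benchmark.
- What the generators do **not** emulate: probe-level artifacts, batch
  effects, missing-at-random patterns, heavy-tailed noise, or correlation
  between baseline expression level and variance. Passing tests therefore
  demonstrate correctness of the statistical machinery under its own
  assumptions, not robustness to microarray-specific artifacts — those
  are expected to be handled upstream by preprocessing.

All generators are pure functions of (parameters, seed); the pipeline
derives every stage's randomness from the single config seed.

## Problem sizes

The bundled checks run at desk scale, chosen to keep the whole suite fast
while leaving comfortable statistical margins: 5000–10000 genes for
null/false-positive-rate checks, 2000 genes for power, 20 seeds of
(p = 30, n = 50) graphs for edge-recovery precision, 50 seeds for
single-edge detection power, and 200 replicates × 1000 permutations for
the evaluation-test calibration.

## Known limitations

- The mixture's κ and η0 are point estimates; with very few gene pairs
  (≪ 100) the edge probabilities are unstable, and the code recommends
  at least 10 pairs.
- Edge probabilities are calibrated against the *shrunken* partial
  correlation scale; they are posterior probabilities relative to the
  fitted null, not frequentist edge-wise error rates.
- Closeness on disconnected graphs is a convention (per component);
  alternative conventions reorder only nodes in small components.
- The permutation test conditions on the observed topology; it evaluates
  label assignment, not the edge-detection procedure itself.
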