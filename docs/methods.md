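# Methods

This note records the statistical model, the synthetic data-generating
process, the numerical choices, and the design decisions taken where the
problem was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The estimand

For a population of timber-producing points, each with environment
*x* (ten covariates plus coordinates) and management class
*T* ∈ {natural production, plantation}, the quantity of interest is the
relative difference in mean burn probability if the *same* points were
managed one way versus the other:

    Δ_rel = 100 · (E[p(x, T=plantation)] − E[p(x, T=natural)]) / E[p(x, T=natural)]

Two aggregations of Δ_rel exist and differ materially:

- **population-level**: ratio of the means over all points;
- **country-pooled**: the unweighted mean of within-country ratios.

These coincide only when countries share a baseline burn rate. With a
homogeneous log-odds effect, low-baseline countries show larger *relative*
effects (the logistic link compresses high probabilities), so the mean of
country ratios exceeds the ratio of means — about 30 percentage points in
the benchmark scenario. The pipeline's pooled group effect is the
country-pooled estimand (a per-country analysis averaged across
countries), so the synthetic ground truth carries **both** numbers and the
recovery benchmark calibrates the country-pooled one to +100%. Comparing a
country-pooled estimate against a population-level truth would mix
estimands and mistake a Jensen gap for bias.

## Synthetic landscapes

The generator emulates the *statistical* structure the analysis assumes,
not any real geography:

- **Covariate fields.** Each covariate is a sum of 3–6 seeded
  low-frequency sinusoids and Gaussian bumps over the extent plus white
  noise (`noise_sd`, default 0.35), optionally correlated across
  covariates through a shared latent field (`covariate_correlation`,
  default 0.3 — the data sources say nothing about the cross-covariate
  covariance, so it is a knob, not an assumption). Fields are z-scored and
  mapped to plausible natural scales (metres, °C, mm, …); the models
  re-standardize internally, so these scales are cosmetic.
- **Lattice points.** Points sit at distinct cell centres of a regular
  lon/lat lattice (≈4 cells per point), so rasterizing management, fire
  year and confidence back to grids is exact and the round-trip test can
  demand >99% agreement.
- **Confounded assignment.** Management is Bernoulli with
  logit⁻¹(propensity coefficients · standardized covariates). In the
  benchmark, plantations preferentially occupy hot, high-fire-weather,
  road-near, gentle terrain — the same directions that raise burn
  probability — giving a naive contrast roughly double the truth.
- **Burn process.** Bernoulli with logit = intercept + linear terms +
  named nonlinear terms (registry: sin, quadratic, saturating tanh, bump)
  + `treatment_log_or`·1[plantation]. The benchmark uses a saturating
  fire-weather effect and a quadratic elevation effect.
- **Independent streams.** Fields, assignment, outcomes, confidence and
  fire years draw from separate named RNG streams spawned from the master
  seed, so changing the outcome model never perturbs assignment — this is
  what allows the treatment effect to be calibrated on the realized
  population *before* burns are drawn.
- **Ground truth.** `true_marginal_difference` forces every point to both
  managements and averages exactly (no sampling); an independent per-point
  loop oracle pins it to 1e-12 in tests. `calibrate_treatment_log_or`
  solves for the log-odds shift hitting a target relative effect by
  bracketing root-finding (the effect is strictly increasing in the
  shift).
- **Labels and confidence.** Countries are equal-width longitudinal
  blocks, biomes latitudinal bands — enough structure for exact matching
  and random intercepts to matter. Classification confidence is
  Beta-distributed with class-specific means (0.80 natural / 0.78
  plantation, concentration 12), so the ≥70% filter removes a meaningful
  ~20% of points.

What the generator does **not** emulate: realistic covariate marginals or
spatial ranges, measurement error in covariates, fire spread (burns are
conditionally independent given covariates), or management misclassification
beyond the confidence scores. Passing recovery tests therefore show that
the *inference chain* is consistent when its assumptions hold — not that
those assumptions hold for any real landscape.

## Accounting rules

- Confidence filter is inclusive (≥ 0.70) and exposed as a flag; the
  tree-cover filter is likewise inclusive at ≥ 0.30 and uses the point's
  own tree-cover value.
- The fire overlay counts a pixel as stand-replacing loss iff its
  fire-loss year is ≥ 2016 (the management snapshot is nominally 2015) and
  the pixel carries a timber class; nodata propagates.
- One-degree cells are anchored at integer degrees, half-open [d, d+1);
  within each (cell, class) stratum sampling is uniform without
  replacement, capped at 5000.
- The country gate is strict: keep iff burned fraction of matched points
  > 0.001.
- Geographic pixel areas use the equatorial cell area scaled by
  cos(latitude) (1° ≈ 111.32 km), accurate to well under 1% against the
  spherical band formula over 0–80°.

## Matching

- Propensity scores come from an in-package IRLS logistic regression of
  plantation membership on the ten standardized covariates (tolerance
  1e-8 on the largest coefficient update, 100 iterations); agreement with
  statsmodels' Newton solver to 1e-6 is a test. Coefficients exceeding 15
  in absolute value on standardized covariates are treated as separation:
  flagged, warned, scores still returned.
- Greedy 1:1 nearest-neighbour matching without replacement: treated
  units in a seeded random order within each exact-biome stratum; distance
  is |Δ logit score| (propensity) or Mahalanobis distance on standardized
  covariates with a ridge-1e-8 pooled covariance (metric choice); the
  caliper is expressed in SDs of the logit propensity score over all
  points and, following the common MatchIt convention, also gates
  eligibility for Mahalanobis matching (switchable). Ties break to the
  lowest control id for reproducibility. A plain-Python reference matcher
  reproduces the pairs exactly on random instances.
- SMD = |mean_T − mean_C| / SD of the treated group *before* matching, so
  before/after values share a denominator; balance rule: every covariate
  < 0.25 after matching.
- Method selection minimizes the maximum after-match SMD, tie-broken by
  larger matched sample, then propensity over Mahalanobis, then the
  smaller caliper.
- Treatment direction: plantation points are "treated" (they are the
  minority class), matched within country only.

## The burn-probability model

- **Basis.** Cubic regression splines in the knot-value parameterization:
  coefficients are function values at k knots (default k = 10, at
  quantiles of the standardized covariate), the penalty is the integrated
  squared second derivative, and the null space is exactly the linear
  functions. Values beyond the knot range extrapolate linearly. A
  sum-to-zero constraint is absorbed (k − 1 columns per smooth). Quantile
  knots closer than 1e-4 of the range are merged (heavily tied covariates
  such as burn history otherwise give near-zero spacings and exploding
  penalties); each block's penalty is normalized to unit largest entry so
  smoothing parameters are comparable across terms.
- **Random effects and interactions** are ridge-penalized dummy blocks
  (the standard mixed-model-as-penalty identity): country and biome
  intercepts, all observed biome×country combinations, biome×management
  products, and per-biome tree-cover smooths sharing a single λ. No
  reference levels are dropped — the penalties make the blocks
  identifiable; under λ → 0 the resulting collinearity with the intercept
  is handled in the EDF computation (below). Coordinates enter as two
  univariate lon/lat smooths rather than a bivariate surface.
- **Fitting.** Penalized IRLS minimizing deviance + Σ λ_t βᵀS_tβ, with
  step-halving on the penalized deviance; convergence at relative change
  < 1e-8 (max 200 iterations). A step that cannot improve beyond ~1e-4
  relative after 30 halvings is treated as converged — at extreme λ the
  penalty term carries O(cond·eps) evaluation noise.
- **EDF.** Per-term effective degrees of freedom are the trace of
  (XᵀWX + S_λ)⁻(XᵀWX) over the term's columns, computed by
  eigendecomposition with a 1e-12-relative spectral cutoff: exactly
  collinear unpenalized directions contribute zero, while a smooth's
  linear null-space direction survives λ as large as 1e12. (A Cholesky
  solve is numerically unstable here precisely in the near-singular cases
  that matter.)
- **Smoothing selection.** GCV = n·Deviance/(n − γ·EDF)² with γ = 1.4,
  minimized by coordinate-wise multiplicative grid search (wide first
  sweep, refined second), warm-starting each fit. γ = 1.4 is the standard
  inflation against GCV's undersmoothing bias; with γ = 1 a strictly
  linear truth was fitted with ~3.4 EDF, with γ = 1.4 it collapses to the
  1-EDF line while a strongly sinusoidal truth keeps ~7.6 EDF. At pipeline
  scale the λs are tied into three groups (all smooths / random
  intercepts / interactions) to keep a full run to seconds; per-term
  selection remains the default elsewhere.
- **Diagnostics.** Residual spatial autocorrelation by Moran's I with
  row-standardized k-nearest-neighbour weights (k = 8) and a two-sided
  permutation p-value (add-one corrected); null expectation −1/(n−1). The
  statistic requires ≥ 30 points for stability. An empirical residual
  variogram (binned semivariance vs distance on a subsample) is written
  alongside as CSV + PNG; a flat curve corroborates the Moran's I verdict.
- One model is fitted per plantation kind; a synthetic scenario is
  single-kind, so a pipeline run fits one pooled model over its retained
  countries.

## Counterfactual simulation

Per country and replicate: sample `n_points` (default 1000) from the
matched points — without replacement within a replicate when enough points
exist, with replacement otherwise — force all of them to each management
in turn, draw Bernoulli burn outcomes per arm (independent draws; a
deterministic expected-count mode exists and is tested to agree in
expectation), and record the burned-count difference. Over `n_reps`
replicates (default 10,000; the test bench uses 500) this yields the mean
difference, percentile 2.5/97.5 CI, a two-sided simulation p-value
p = 2·min(share ≤ 0, share ≥ 0) with add-one correction, and the relative
percentage computed from replicate-averaged arm means (per-replicate
ratios are unstable at low burn counts). Probabilities are computed once
per point and indexed per replicate, so the cost is the random draws.

The pooled group effect is the unweighted mean of member countries'
relative percentages; its p-value is a two-sided sign-flip permutation
test on the countries' mean differences (9999 flips), and its 95% CI is
the percentile interval of the across-country mean of per-replicate
relative differences — the same mean-of-ratios estimand as the point
estimate. This CI reflects counterfactual-stage noise (point sampling +
Bernoulli draws), not model-estimation uncertainty; the recovery benchmark
measures its actual coverage empirically.

## Benchmark problem sizes

The recovery scenario uses 40,000 points over 10 countries and 3 biomes
with the counterfactual at 1000 × 500 replicates; the null-calibration
scenario uses 8,000 points over 5 countries. These sizes give matched
samples of ~1000 pairs per country — enough for stable balance and a
well-conditioned fit — while a full replicate batch completes in minutes
on one CPU. `scripts/acceptance.py` runs 10 recovery and 25 null
replicates; the test suite runs 25 and 100.

## Known limitations

- GCV with tied λ groups is coarser than per-term REML; it is
  deterministic and adequate here, but λs are not comparable to mgcv's.
- The counterfactual CI understates total uncertainty (no GAM estimation
  error, no matching variability); empirical coverage of the pooled CI is
  measured, not guaranteed.
- Greedy matching is order-dependent by design (seeded); optimal matching
  is out of scope.
- The raster layer handles shared-grid overlays only; there is no
  reprojection, and grid I/O is plain-text ASCII grids.
- Burn outcomes are conditionally independent across points; real fire
  spread induces spatial dependence the lon/lat smooths only partially
  absorb.
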