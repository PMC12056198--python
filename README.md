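# firematch

Do timber plantations burn more than natural production forests once you
control for where they are? Plantations are not planted at random — they
sit on different terrain, in different climates, closer to roads — so the
raw contrast in stand-replacing-wildfire rates between management types is
confounded. `firematch` implements the full observational inference chain
for this question and stress-tests it on synthetic landscapes where the
true effect is known:

1. **Accounting** — classification-confidence (≥ 70%) and tree-cover
   (≥ 30%) filters, post-2015 fire-year overlay on management grids,
   burned-area ledgers, and capped stratified sampling (≤ 5000 points per
   management class per one-degree cell).
2. **Matching** — per-country 1:1 greedy nearest-neighbour matching of
   plantation points to natural-production controls, propensity-score and
   Mahalanobis metrics under calipers of 0.2 / 0.5 SD of the logit
   propensity score, exact on biome; the candidate with the best
   worst-covariate balance wins, and a country is kept only if every
   covariate's after-match standardized mean difference is < 0.25 and
   > 0.1% of its matched points burned.
3. **Modelling** — a penalized-spline binomial GAM (logit link):
   management class as a parametric term, cubic regression spline smooths
   of the ten covariates plus lon/lat, ridge-penalized random intercepts
   for country and biome, and biome×country / biome×management /
   biome×tree-cover interactions. Smoothing parameters by EDF-inflated GCV.
4. **Counterfactual** — Monte-Carlo g-computation: every sampled point is
   forced to both managements, burn outcomes are simulated under each, and
   the burned-count differences over repeated samples of 1000 points give
   each country's mean effect, 95% CI and relative percentage, pooled to a
   group mean with a sign-flip permutation p-value.

The model for point *i* with covariates *x*, country *c*, biome *b* and
management indicator *T*:

    logit P(burned_i = 1) = β·T_i + Σ_j f_j(x_ij) + f_lon(lon_i) + f_lat(lat_i)
                            + u_c + v_b + (biome × country, management, tree-cover terms)

with cubic-spline smooths *f* and penalized (random) intercepts *u, v*.
The quantity reported per country is the relative percentage difference
100·(p̄_plantation − p̄_natural)/p̄_natural of the simulated mean burn
probabilities under the two forced managements.

The synthetic generator (`firematch.synthetic`) draws smooth spatial
covariate fields, assigns management with a covariate-dependent propensity
(so assignment is confounded by construction), simulates burns from a
logistic model with a known management log-odds shift, and computes the
exact ground-truth effect by brute force — which is what makes end-to-end
parameter-recovery tests possible.

## Worked example

The numbered scripts under `analysis/` run the benchmark study: a
confounded 40,000-point landscape over 10 countries whose true pooled
relative effect is calibrated to exactly +100%.

```bash
python analysis/01_simulate.py      --seed 42
python analysis/02_filter_sample.py --seed 42
python analysis/03_match.py         --seed 42
python analysis/04_fit_gam.py       --seed 42
python analysis/05_counterfactual.py --seed 42
python analysis/06_report.py
```

Output of the chain (seed 42):

```
generated 40000 points over 10 countries (37.1% plantation, burn rate 15.5%)
treatment log-odds calibrated to 0.9822 -> true pooled relative effect +100.0%
naive unmatched relative burn-rate contrast: +198.3% (confounded)
retained 10 of 10 countries, 19824 matched points; worst after-match SMD 0.052 (< 0.25)
fitted 19824 matched points: deviance 13598.0, total EDF 60.4, converged=True
management log-odds coefficient +0.972 (odds ratio 2.64)
residual Moran's I -0.0064 vs null -0.0003 (p = 0.368) on a 4000-point subsample
pooled temperate effect +100.5% (95% CI +90.0..+111.2, p = 0.0016) over 10 countries
```

Read: the raw burn-rate contrast (+198%) nearly doubles the true effect
because plantations were planted on fire-prone ground; after matching
(all covariates balanced to SMD ≤ 0.05) and spline adjustment, the
counterfactual simulation recovers +100.5% against a known truth of
+100.0%, with the truth inside the 95% interval. Per-country effects range
from +50% to +142% because countries differ in baseline burn probability
(the same log-odds shift implies a larger relative effect where burning is
rarer).

The same pipeline is scriptable via the `firematch` CLI
(`simulate | overlay | sample | match | fit | counterfactual | run`), e.g.
`firematch run --seed 42 --n-reps 500 --out results/cli_run`.

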