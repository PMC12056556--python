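# reefhdr

Quantitative synthesis of heterogeneity–diversity relationships (HDRs) on
rocky reefs.  Habitat heterogeneity — rugosity, cover of structural
features, variation in feature sizes — is measured in incompatible units
across studies; `reefhdr` standardizes heterogeneity gradients to a common
[0, 1] scale within each within-study *HDR group*, converts responses to
per-observation log response ratios against the lowest-heterogeneity
baseline, and fits quadratic linear mixed models to ask how community
responses (richness, diversity, abundance, biomass) and ecological
processes (grazing, predation, recruitment, body size) change along
heterogeneity gradients, and how that change depends on the heterogeneity
facet, the organismal group, and the environment.

It is written for ecologists running meta-analyses of habitat-structure
experiments, and for methodologists who want a tested reference
implementation of the lnRR + mixed-model pipeline with a synthetic
multi-study generator for validation.

## The model

For observation *i* in HDR group *j* of study *s*:

    lnRR_i = ln( y_i / mean(y at the lowest heterogeneity level of group j) )

    lnRR_i = β0 + β1·x_i + β2·x_i² + covariates
             + u0_s + u1_s·x_i + w_j + ε_i

where x ∈ [0, 1] is the standardized heterogeneity, (u0, u1) is a
correlated study-level random intercept and slope, w_j an HDR-level
intercept nested in study, and ε residual noise.  The CV of the raw
heterogeneity values enters as a covariate (its interaction with x is kept
only when significant; non-significant candidate interactions are removed
by backward elimination under ML, final inference is REML).  Each fit
reports coefficient tests, variance components, marginal and conditional R²
(fixed-effect vs total variance explained), and a shape classification of
the fitted curve: linear, saturating (vertex −β1/2β2 ≥ 1), hump-shaped
(vertex inside the gradient), flat or u-shaped.

## Worked example

```python
from reefhdr import (SimulationScenario, simulate_dataset, prepare_groups,
                     run_facet_suite)

# 40 synthetic studies, 6 HDR groups each, known generating curves
obs, truth = simulate_dataset(SimulationScenario(seed=1))
groups, log = prepare_groups(obs)          # group -> standardize -> lnRR
res = run_facet_suite(groups, "richness")  # one mixed model per facet
print(res.fits["substrate_3d_amount"].summary())
```

prints (abridged):

```
HDR quadratic mixed model
  formula:   lnrr ~ x + x2 + het_cv + x:het_cv
  estimation: REML; df method: residual; converged: True
  n_obs=960  n_hdr=40  n_study=40

           estimate      se  tvalue   df  pvalue
term
Intercept   -0.1046  0.0658 -1.5907  955  0.1120
x            0.8814  0.1633  5.3956  955  0.0000
x2          -0.4858  0.1032 -4.7093  955  0.0000
het_cv       0.1587  0.1299  1.2209  955  0.2224
x:het_cv     0.5115  0.2568  1.9921  955  0.0466

Variance components:
  study_intercept_var           0.00417
  study_slope_var               0.03664
  study_intercept_slope_cov     0.01122
  hdr_intercept_var             0.00170
  residual_var                  0.08936

R2 marginal = 0.2968   R2 conditional = 0.4743
shape: hump (vertex at x = 0.907)
Dropped terms: organismal_group (single observed level)
```

The generating curve for this facet is β1 = 1.2, β2 = −0.6 — a saturating
form with the vertex exactly at the top of the gradient.  The significant
x and x² terms mark a positive, decelerating heterogeneity effect; the R²
pair says fixed effects explain ~30% of lnRR variance and study/group
structure brings the total to ~47%.  In this run the x:CV interaction was
retained (p = 0.047, a borderline call the pruning audit trail records),
so `x` is the slope at CV = 0 and the fitted vertex lands just inside the
gradient ("hump" rather than "saturating") — refitting with the bare
quadratic gives β1 = 1.12 ± 0.11, β2 = −0.49, within sampling error of
the truth.

A command-line interface wraps the same pipeline:

```sh
reefhdr simulate --seed 1 --out sim/
reefhdr fit --input sim/dataset.csv --out results/ \
        --suite facet_richness --exclude drop_confounded
reefhdr recover --replicates 50 --seed 1 --out recovery/
```

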