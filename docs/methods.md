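# Methods

## Problem and data model

`reefhdr` synthesizes heterogeneity–diversity relationships (HDRs) across
many rocky-reef studies whose heterogeneity metrics, units and experimental
designs differ.  The unit of synthesis is the *HDR group*: all observations
within one study that share a facet of heterogeneity (substrate 3D amount,
substrate 2D amount, substrate complexity, feature size, feature variation,
feature richness), one response metric, one organismal group, and one
site/date/substrate context.  When a grouping cell would contain fewer than
three replicates, the grouping is extended by collapsing site, then date,
then substrate context, in that order, until every group meets the
threshold; a cell that stays too small even fully collapsed is dropped and
logged.  The collapse order is a convention — the three keys are exchangeable
a priori — chosen for determinism.  Groups are additionally keyed by
response metric and organismal group because mixing metrics within one
group would corrupt the effect-size baseline.

## Standardization

Within each HDR group, continuous heterogeneity is z-transformed and then
min–max mapped to [0, 1].  The composition of two affine maps is affine, so
the result is identical to a plain min–max rescaling; the package asserts
this equivalence against an independent oracle rather than relying on it
silently.  Discrete ordinal descriptors map level *i* of *k* to
(i−1)/(k−1), which reproduces the 0/1 and 0/0.5/1 conventions for two- and
three-level classifications and extrapolates even spacing to deeper
orderings.  The coefficient of variation (CV = sample SD / mean, n−1
denominator) of the *raw* values, in the study's original units, is carried
as a covariate describing how broad a gradient each group spans.  For
discrete descriptors no original units exist; their CV is computed on the
mapped values and flagged (`cv_on_mapped`).  Sample rather than population
SD is used throughout because study-level data are samples.

Standardization is performed within the HDR group (not within study): the
group is the unit on which the gradient is defined, and per-group
standardization keeps gradients comparable when one study spans several
facets or metrics.

## Effect sizes

The response is the per-observation natural-log response ratio,
lnRR_i = ln(y_i / mean(min(y))), where the denominator is the arithmetic
mean response over all observations at the group's lowest standardized
heterogeneity level.  Baseline observations are retained as data points:
their lnRR scatters around ln(geometric mean / arithmetic mean) ≤ 0 and
carries residual-variance information.  Zero responses cannot be
log-transformed; at the baseline they enter the baseline mean (a baseline
mean of exactly zero invalidates the group), elsewhere they are excluded
with a logged count rather than offset-corrected — any offset constant
would be arbitrary and distorts small ratios.

## Model

The core model, fitted separately per stratum (facet, organismal group, or
ecological process), is a linear mixed model

    lnRR ~ β0 + β1·x + β2·x² + covariates
           + (1 + x | study) + (1 | HDR group) + ε

with x the standardized heterogeneity, a correlated study-level intercept
and slope, an HDR-level intercept nested in study, and i.i.d. residuals.
The quadratic term is always present with the linear term.  Candidate
interaction terms (the CV × x term, metric/facet interactions, and the
environmental candidates latitude × season, x × substrate type, and
x × latitude) are pruned by backward elimination under ML: refit, remove
the interaction with the largest joint Wald p-value above α = 0.05, repeat.
Main effects, x and x² are never removed.  The final model is refitted by
REML.  Estimation is delegated to statsmodels `MixedLM`; x × latitude is
included among the environmental candidates because latitude moderation of
the heterogeneity *effect* (a slope, not a level, shift) is the quantity of
ecological interest there.

Wald t statistics use residual degrees of freedom (n_obs − n_fixed);
Satterthwaite approximations are not available in the backend, and the df
method is recorded in the results metadata.  With the study counts used
here this choice is mildly anti-conservative for study-level terms, which
is visible in the type-I calibration (measured ≈ 5–7% at a nominal 5%).

Optimizer strategy: L-BFGS first; its convergence flag is unreliable
exactly at variance boundaries (common under null or noise-free data), so a
flagged non-convergence is polished with Powell starting from the L-BFGS
solution, then fresh Powell and CG restarts.  Singular fits (a variance
component at zero) are retained with a warning, matching standard mixed
-model practice; true non-convergence is surfaced as an error object in
suite results, never silently.

### Variance explained

Marginal R² = var_fixed / (var_fixed + var_random + var_residual) and
conditional R² = (var_fixed + var_random) / (same), where var_fixed is the
variance of the fixed linear predictor over the estimation sample and
var_random evaluates the study intercept + slope structure at the sample's
x distribution: τ00 + 2·τ01·E[x] + τ11·E[x²] + ω² (HDR intercept).  A
negative total (possible under strongly negative intercept–slope
covariance) is clipped at zero.

### Shape classification

The fitted quadratic is classified at significance level α: non-significant
curvature gives flat / linear increasing / linear decreasing by the linear
term; significant negative curvature gives a vertex x\* = −β1/(2β2), called
a *hump* when 0 < x\* < 1 and *saturating* when x\* ≥ 1 (the curve rises
throughout the observed gradient and levels off at or beyond its top);
significant positive curvature is u-shaped.  Boundary conventions: x\*
exactly 1 is saturating; x\* ≤ 0 is decreasing throughout.

### Contrasts

Pairwise moderator-level contrasts are Wald tests of design-row differences
at the estimation sample's mean x, Holm-adjusted, with a compact letter
display assigned to maximal runs of mutually non-significant levels in
estimate order.

## Suites

Four batteries mirror the analysis objectives: (1) per-facet models of
richness and of abundance for pooled micro- and macroinvertebrate data,
with organismal group and CV as covariates plus per-HDR species count in
abundance models; (2) per-organismal-group models pooling community metrics,
with the four minor facets pooled as `other_pooled` and response-metric
interactions as prunable candidates; (3) per-process models (grazing,
predation, recruitment, body size) with facet and organismal group as
covariates; (4) the environmental re-runs adding substrate type, depth
zone, centred absolute latitude and season, with interaction candidates
admitted only when every participating factor level is observed in at
least two studies.  Strata are always fitted independently; strata with
fewer than two studies are skipped with a recorded reason.

## Sensitivity and publication bias

Five composable, idempotent exclusion filters: studies flagged large (or,
absent flags, above the 95th percentile of per-study observation count —
the flagging of "large" is inherently ingest-side information, so the
quantile is only a leverage-based fallback), HDR groups with fewer than
four observations, discrete descriptors, multi-facet studies, and studies
whose gradients are confounded with site/date/substrate.  Each rule is
applied independently, the suite re-run, and per-stratum changes in β1, β2
and significance tabulated.  Publication bias is probed by adding
standardized sample size and publication year as fixed effects; constant
covariates are dropped with a note.

## Synthetic data generator

The generator emulates the assumed data structure with known truth:
responses y = B·exp(u0_s + w_j + slope·x + β2·x² + ε) with
slope = β1·(group multiplier) + u1_s + environmental slope terms, (u0, u1)
bivariate normal across studies, w_j normal across HDR groups, ε normal —
i.e. multiplicative lognormal noise, chosen so that lnRR is the natural
response scale.  x = 0 is always present, so the lnRR baseline is always
defined.  Raw heterogeneity is emitted through per-study affine unit
transforms raw = a_s·x + b_s (a_s ∈ [0.5, 50], b_s ∈ [0, 10]), exercising
the standardization stage non-trivially; a configurable fraction of HDRs
carries discrete ordinal labels on the even grid instead.

Because the lnRR baseline is computed within each HDR group, the study and
HDR intercepts u0 and w cancel exactly in the effect sizes; what survives
is the slope structure plus a shared baseline-sampling term per group.  The
fitted intercept variance components therefore absorb baseline noise rather
than the generating τ0²/ω², and recovery is assessed on β1/β2, which the
pipeline preserves.  This is a property of the lnRR design itself, not an
artefact of the generator.

Default scenario: 40 studies × 6 HDRs/study × 8 levels × 3 replicates
(5,760 observations), τ0² = 0.04, τ1² = 0.04, ρ = 0, ω² = 0.01, σ² = 0.09,
baseline scale 10, 10% discrete HDRs.  Facet curves mirror the qualitative
ordering reported for rocky reefs — substrate 3D amount strongest and
saturating (β1 = 1.2, β2 = −0.6, vertex exactly at the top of the
gradient), feature richness null, the remaining facets intermediate — and
the slope multipliers of the two well-studied invertebrate groups are 1.0
so that each facet stratum's slope truth is identifiable as the facet's own
β1.  Environmental moderator effects default to zero and are switched on by
scenario variants; they act on the slope because intercept-type effects
cannot survive the within-group baseline (see above).

What the generator does *not* emulate: empirical distributions of real
heterogeneity metrics, unbalanced designs, taxa, geography, or selection
effects of the literature.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the stated model, not
robustness to model misspecification in real data.

## Validation problem sizes

Validation runs use these sizes, chosen to make each check statistically
informative at desk scale: noise-free exactness at the default scenario
dimensions; stochastic recovery with 200 replicates of the default
scenario; type-I calibration and CV-interaction pruning with 200 replicates
at 30 studies × 4 HDRs × 5 levels × 2 replicates; the confounded-study
sensitivity direction with 100 replicates at 18 studies (one third
confounded, slope inflation 2×).  The standalone summary script
(`scripts/acceptance.py`) re-runs the same computations with 60–100
replicates per block.

## Known limitations

- Residual-df Wald tests rather than Satterthwaite; study-level moderator
  tests are slightly liberal at small study counts.
- The backward-elimination p-values are not corrected for selection; the
  audit trail exposes every removal so alternative selections can be
  replayed.
- CV for discrete descriptors is only a within-convention measure, not
  comparable with raw-unit CVs; it is flagged accordingly.
- The quadratic form cannot represent asymptotes; "saturating" here means a
  vertex at or beyond the gradient top, not a true plateau.
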