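# Methods

`clocktraj` characterises how the CpG sites that make up adult epigenetic
clocks behave over the first two decades of life: whether they change,
whether the change is non-linear, how early individuals start to differ,
and whether "clock" sites carry more of these developmental features than
the rest of the methylation array.  Because individual-level cohort data
of this kind are access-restricted, the package pairs the analysis stack
with a synthetic cohort generator that emulates the study design and
carries per-site ground truth, so every stage is testable end to end.

## Longitudinal models

For each CpG site, methylation beta values `y_ij` of individual `i` at age
`t_ij` (years) are modelled with two maximum-likelihood linear mixed
models:

**Model 1** (overall change, differences at birth)

    y_ij = (b0 + u0_i) + (b1 + u1_i) t_ij + covariates + e_ij

with `(u0, u1)` bivariate normal (SDs `sd_intercept`, `sd_slope`,
correlation `rho`), and `e_ij ~ N(0, sd_resid^2)`.  The random intercept
measures inter-individual differences at birth; the random slope,
differences in rate of change; their correlation links the two.

**Model 2** (non-linear change) adds truncated-linear terms `(t-6)+` and
`(t-9)+`, fixed and random, so the population slope and each individual's
slope may change at 6 and 9 years.  The period slopes are

    s1 = b1,   s2 = b1 + d6,   s3 = b1 + d6 + d9,

with standard errors from linear contrasts of the fixed-effect
covariance.  The knots are fixed at 6 and 9 years for both cohorts even
though one cohort visits at 7.5/17: the pooled analysis uses a common
basis.

Covariates: sex, gestational age (z-scored), batch plate (dummy-coded),
cohort, and six estimated white-blood-cell proportions (z-scored).
Nucleated red blood cells are specific to cord blood and are not used as
a covariate.  Continuous covariates are z-scored over the analysis
sample; a constant column is dropped with a warning and genuine
collinearity is an error naming the columns.

### Estimation

Fitting thousands of sites requires a per-site fit in tens of
milliseconds, so the engine (`clocktraj.mixedlm`) exploits the data
shape: at most three observations per individual, hence a marginal
covariance that factorises into thousands of 3x3 blocks.  The profiled
deviance (fixed effects solved by GLS at every step) is evaluated with
closed-form cofactor inverses of the batched blocks, and the 3-6 variance
parameters are optimised by L-BFGS-B with an analytic gradient on an
unconstrained scale: log-SD per random effect and residual, atanh for
the intercept-slope correlation.  Restarts from three deterministic
starting scales run until one converges.  Box constraints keep every
block numerically well conditioned; in particular the residual SD cannot
fall below ~0.25% of the OLS residual scale, which excludes a degenerate
spike of the likelihood in which the random effects interpolate the data.
Nested refits warm-start from the full fit, and if a reduced model ever
beats the full one (optimizer noise), the full model is restarted from
the embedded reduced solution so the nesting inequality holds.

The fit is cross-checked in the test suite against `statsmodels` MixedLM
(ML) on the same model: log-likelihoods agree to ~1e-3 and fixed effects
to ~1e-5 on balanced and unbalanced designs.

### Inference

* Fixed effects: large-sample Wald z tests (the convention of array-scale
  EWAS practice).
* Random effects: likelihood-ratio tests against the fit with the term
  removed.  Because a variance sits on the boundary of its parameter
  space under the null, the statistic is referred to the 50:50
  chi-bar-square mixture of chi-square(q-1) and chi-square(q), where q is
  the number of covariance parameters removed (q = 2 for a term tied to
  the free correlation, q = 1 for an independent slope-change term).
  Calibration is verified by simulation: across 1000 null sites the
  empirical type-I error at alpha = 0.05 falls within [0.03, 0.07].
* Intercept-slope correlation: LRT of the free-correlation fit against
  the diagonal fit, plain chi-square(1) (interior parameter).  When
  either variance component is effectively at its boundary (variance
  contribution < 1% of residual variance on the scale of its design
  column) the correlation is undefined and reported as such with p = 1.
* Site-level significance uses a fixed threshold of 1e-7, the
  Bonferroni-style cutoff for an array of ~473,864 sites, configurable.

LRT statistics may come out marginally negative through optimizer noise;
deficits up to 1e-3 in the statistic are clamped to zero (logged), larger
ones raise an error as genuinely non-nested inputs.

## Feature taxonomy

A site *changes* when the Model 1 age effect passes the site-level
threshold, with direction from its sign (the single dichotomy is used
even for non-linear sites).  *Non-linear at 6/9* requires the Model 2
slope-change fixed effect; *change-then-stable at 6* additionally
requires a significant pre-knot slope, a non-significant post-6 slope and
no slope change at 9 — the contrast-based reading of "changed, then
remained stable".  Variability flags (`var_at_birth`,
`rate_var_from_birth/6/9`) come from the random-effect LRTs.  Because it
is not stated whether an aggregate "non-linear" count should use either
knot or a joint test, the per-knot flags and their union
(`nonlinear_any`) are all emitted.  Failed or degenerate fits carry no
flags and are excluded from numerators and denominators alike.

## Birth-adulthood correlation

Methylation is residualised by OLS at each time point for batch, WBC
proportions, gestational age and sex, and the Pearson correlation of the
residuals is taken over individuals observed both at birth and at their
oldest visit in the cohort whose schedule reaches at least 15 years.
Pairing requires both visits; there is no imputation.  `r^2` is reported
as the share of adult variance predictable at birth.  Note that with few
pairs and many covariate levels, residualisation itself shrinks the
correlation (it removes a fraction ~p/n of the shared signal); the
closed-form comparisons in the tests use designs where this effect is
small.

## Enrichment

Every enrichment is a 2x2 table — clock membership against a binary site
property — over successfully fitted sites of the measured array; clock
sites absent from the array universe are kept in the clock definition but
excluded from these denominators.  The two-sided p is the exact
hypergeometric test.  The odds ratio is the conditional maximum-
likelihood estimate with an exact 95% interval (matching the output
format of standard exact-test software); for tables whose smallest margin
exceeds 1000 the sample odds ratio `ad/bc` with a Woolf interval is
substituted and flagged, the exact p being retained — at those counts the
two estimators agree within ~2% (verified by simulation) and the exact
interval is needlessly expensive.  Zero cells yield an infinite (or zero)
estimate with a finite one-sided bound.  The telomere-length clock's
coefficients are negated before any direction-based analysis so that a
positive coefficient always means "contributes positively to the
age(ing) estimate".  Direction consistency crosses coefficient sign with
developmental direction over unmixed-sign, significantly changing sites
(a variant over all sites is available, since the restriction is implied
rather than stated).

Annotation enrichment applies the same machinery to externally supplied
site sets (meQTL-associated CpGs, prenatal-exposure EWAS hits, WBC
panels) after intersecting them with the universe.

## Matched backgrounds

Because low-variability sites are unlikely both to enter a clock and to
show dynamic features, each enrichment is re-run against a matched
background: greedy nearest-neighbour selection without replacement of
`ratio` non-clock sites per clock site (default 100 at full scale) on a
scalar site property — the fitted random-intercept SD for the
"differences at birth" analyses, the absolute fitted age effect for the
"change" analyses (absolute, so increasing and decreasing sites pool;
signed matching is a config option).  Treated sites are processed in
descending feature order with ties broken by id, so matching is fully
deterministic.  Standardised mean differences before/after matching are
reported as the balance diagnostic.

## Synthetic cohort generator

The generator emulates a two-cohort longitudinal methylation study:

* cohort A: 1399 individuals, visits at mean ages 0, 6.0 (SD 0.5) and
  9.8 (SD 0.3) years, 2333 samples;
* cohort B: 949 individuals, visits at 0, 7.5 (SD 0.2) and 17.1 (SD 1.0)
  years, 2686 samples;

totalling 2348 individuals and 5019 samples under the defaults.  Missing
visits are scheduled deterministically from the seed to hit the
per-cohort sample counts exactly, never emptying an individual.  Betas
are generated on the linear beta scale as the sum of a piecewise-linear
mean (knots at 6 and 9), correlated random intercept/slope, independent
random slope changes, additive meQTL dosage effects (Hardy-Weinberg
genotypes), a binary prenatal-exposure effect, covariate effects and
Gaussian noise, then clipped to [0, 1]; defaults keep the clipping
fraction below 1% and the fraction is logged.  Site archetypes (flat,
linear, knee at 6, knee at 9) are drawn with largest-remainder exact
counts from a mixture whose defaults (0.48/0.41/0.08/0.03) mirror
array-wide prevalences of change and non-linear change.  Closed-form
moments (variance at any age, covariance between ages) are exported for
oracle tests.

What the generator does *not* emulate: probe-level microarray noise,
batch structure beyond a categorical shift, the cord-versus-peripheral
blood tissue change at the first knot, sex chromosomes, and spatial
correlation between neighbouring CpGs.  Passing tests therefore show the
statistical machinery is correct under the stated generative model, not
that the biological findings would reproduce on real arrays.

Reported minimum-detectable-change figures for designs of this size are
quoted inconsistently on two scales (0.0025% per year, which over 18
years is only ~0.045%, versus 0.025% per year, which reaches ~0.45%);
the generator exposes both readings as presets
(`DETECTABLE_SLOPE_PRESETS`) and takes no side.

## Problem sizes used in validation

The validation suite runs scaled-down designs chosen to keep Monte-Carlo
error well inside each tolerance: 100 sites at 300 x 3 for the OLS
degeneracy check (on a balanced self-design, where GLS and OLS coincide
exactly for any fitted covariance — the regime in which a 1e-6 agreement
is a property of the solver rather than of sampling noise); 200
archetype-site fits (100 truths, each with a noise draw and its
antithetic mirror about the generative mean, so the bias estimate's
sampling noise cancels and only systematic error is measured) and 1000
null sites at 500 x 3 for recovery and LRT calibration;
10,000 individuals for moment checks; and a 2000-site, 250-individual
cohort for the end-to-end designed-enrichment run, with the
controls-per-treated ratio at 8 (a 2000-site universe cannot support
100:1 matching).  Thresholds match the full-scale analysis (site-level
1e-7, enrichment 0.05).

## Known limitations

* Wald fixed-effect tests are large-sample; no small-sample df
  correction is applied (out of scope).
* The Model 2 random-effect covariance is block-structured (correlated
  intercept/age, independent knee terms); the fully unstructured 4x4
  alternative is unstable at three visits per individual and is not the
  default.
* REML is not offered; all fits are ML, matching the stated estimation
  choice of the analysis the pipeline mirrors.
* The exact-OR fallback threshold (smallest margin 1000) is a speed/
  precision trade, not a statistical boundary; both routes are exact in
  p.
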