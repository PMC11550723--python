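# clocktraj

**Developmental trajectories of epigenetic-clock CpG sites.**

Epigenetic clocks — Horvath, Hannum, Weidner, Zhang's elastic net,
PhenoAge, DNAmTL, DunedinPACE — are weighted sums of DNA-methylation beta
values at selected CpG sites, trained in adults to predict age or
age-related outcomes. How those sites behave *before* adulthood is
largely unknown. `clocktraj` implements, as a tested and reusable
pipeline, the analysis required to find out from longitudinal cohort
data: per-site piecewise linear mixed models from birth to early
adulthood, a developmental-feature taxonomy, birth-to-adulthood
correlation of residualised methylation, and Fisher-exact enrichment of
clock versus non-clock sites with covariate-matched background
sensitivity analyses.

Individual-level data of this kind are access-restricted, so the package
ships a synthetic two-cohort generator with per-site ground truth (2348
individuals contributing 5019 samples at the full-scale defaults, visits
at mean ages 0/6.0/9.8 and 0/7.5/17.1 years). Every downstream stage is
validated against that known truth.

## The models

For each CpG site with beta values `y_ij` (individual `i`, age `t_ij`):

* **Model 1** — `y = (b0 + u0_i) + (b1 + u1_i) t + covariates + e`, with
  correlated random intercept `u0` (inter-individual differences at
  birth) and random slope `u1` (differences in rate of change).
* **Model 2** — adds fixed and random truncated-linear terms `(t-6)+` and
  `(t-9)+`, so slopes can change at 6 and 9 years; period slopes are
  `s1 = b1`, `s2 = b1 + d6`, `s3 = b1 + d6 + d9`.

Both are fitted by maximum likelihood with a batched per-individual
block solver (see `docs/methods.md`). Fixed effects get Wald tests;
variance components get boundary-corrected likelihood-ratio tests
(50:50 chi-bar-square mixture); sites are classified at a fixed
site-level threshold of `1e-7`. Enrichment of clock sites for any binary
feature uses the exact hypergeometric test with a conditional-MLE odds
ratio and exact 95% CI.

## A worked example

```bash
python examples/04_classify_and_enrich.py
```

runs the full pipeline on a 300-site synthetic study whose "clocks"
deliberately over-sample sites with high intercept variance, and prints:

```
feature                      all sites first-gen clock
changes                           0.52            0.48
var_at_birth                      0.30            0.72
rate_var_from_birth               0.02            0.04
nonlinear_at_6                    0.05            0.00

enrichment (clock vs all non-clock sites):
  first         OR=7.06 [2.68, 20.85] p=8.67e-06
  second_third  OR=4.78 [1.70, 14.71] p=1.52e-03

after matching the background on the fitted intercept SD:
  first         OR=1.26 p=8.11e-01 (SMD 1.03 -> 0.17)
  second_third  OR=1.00 p=1.00e+00 (SMD 0.84 -> 0.05)
```

Reading: 72% of the designed first-generation clock sites show
significant inter-individual differences at birth versus 30% of all
sites, an odds ratio of ~7 — and after re-drawing the background from
non-clock sites matched on the fitted random-intercept SD (standardised
mean difference collapsing from 1.0 to 0.17), the enrichment vanishes,
exactly as designed. The other examples walk through the clock registry
(`01`), the cohort generator (`02`), a single-site model fit (`03`) and
the birth-to-adulthood correlation (`05`).

The same stages are available as a CLI:

```bash
clocktraj simulate --out run/ --seed 1 --n-sites 200
clocktraj full --out run/ --seed 1
```

Note on the bundled clock files: the seven coefficient CSVs under
`src/clocktraj/data/synthetic_clocks/` are *synthetic stand-ins* — their
per-clock site counts (353/71/102/514; 513/140/173) and overlap
structure reproduce the published clocks' bookkeeping, including the 967
unique first-generation and 821 unique second/third-generation sites,
but the CpG identifiers and coefficient values are generated. Real
coefficient tables in the same two-column format drop in directly via
`load_clock`.

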