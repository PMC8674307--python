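# Methods

## The problem and the data model

A multi-site FC study yields, per subject j at site i, a vector of
connectivity features y_ijv (v indexes ROI pairs). The package's central
container is the subjects × V feature table of Fisher-z values,
V = R(R−1)/2 upper-triangle entries of an R×R Pearson correlation matrix in
row-major, 0-based order with the diagonal excluded (Fisher z of r = 1 is
infinite, so unit correlations are never stored; |r| is clipped to
1 − clip_eps, default 1e−7, before atanh — finite output, negligible bias).

All methods assume the additive/multiplicative site-effect model on the
z scale:

    y_ijv = α_v + X_ij'β_v + γ_iv + δ_iv ε_ijv

with covariates X (age in years, sex coded male=0/female=1, diagnosis coded
control=0/patient=1 — the codings fix the sign conventions of fitted
coefficients), additive site effects γ_iv and multiplicative site effects
δ_iv.

## Stage order and provenance

The pipeline enforces Fisher z → age/sex residualization → harmonization.
Every table carries an ordered provenance list (`fisher_z`, `residualized`,
`swd`/`glm_full`/`combat`), and harmonization refuses tables that are not
z-scale (unless forced) or that were already harmonized — double application
is a silent-corruption risk in file-based workflows.

Residualization fits each feature on intercept + age + sex by OLS and, by
default, adds the fitted intercept back so harmonized FC values keep their
physical level (grand-mean-centered features lose their interpretable scale).
Whether the original study kept the intercept is not stated; Hedges' g is
location-invariant, so effect-size comparisons are unaffected either way. A
`keep_level=False` / `--pure-residuals` option returns raw residuals.
Mass-univariate OLS is solved with a single vectorized least-squares call
across all features; designs are checked for full column rank.

## The three harmonizers

**SWD.** m_i = mean of all features of all subjects at site i (one scalar per
site); output y − m_i. Consequences, all tested: each site's grand mean is
exactly 0 afterwards; the transform is idempotent; within-site group-mean
differences and single-site effect sizes are invariant (to ~1e−12 — a scalar
subtraction precedes the means, so literal bit equality is not attainable in
floating point). Sites with one subject are allowed with a warning (their
mean is degenerate).

**GLM.** Per feature, OLS on intercept, age, sex and reference-coded site
indicators (first site in sorted order is the reference). The default output
subtracts the full fitted value — the residual, orthogonal to every design
column. A `site-only` mode subtracts just the site-indicator component,
preserving level and covariate structure. The design deliberately contains no
diagnosis term (matching how the method is used in practice); under
site-imbalanced diagnosis proportions the site indicators therefore absorb
part of the between-group contrast — the mechanism quantified in the tests.

**ComBat.** Parametric empirical Bayes in four steps:

1. Per feature, OLS with one indicator per site plus covariates (age, sex,
   and diagnosis — the covariate of interest that must be protected). Site
   intercepts are re-expressed about their sample-size-weighted mean α̂_v,
   enforcing Σ_i n_i γ̂_iv = 0; pooled variance σ̂²_v is the mean squared
   residual of the full fit (1/n convention).
2. Standardize z_ijv = (y_ijv − α̂_v − X'β̂_v)/σ̂_v.
3. Per site: γ̂_iv = within-site mean of z, δ̂²_iv = within-site sample
   variance (n−1). Hyperpriors by method of moments across features: normal
   prior (γ̄_i = mean_v γ̂_iv, τ̄²_i = var_v γ̂_iv) for location and
   inverse-gamma (λ_i = (m² + 2s²)/s², θ_i = (m³ + ms²)/s² from the mean m
   and variance s² of {δ̂²_iv}) for scale. Iterated conditional updates

       γ*_iv = (n_i τ̄²_i γ̂_iv + δ²*_iv γ̄_i)/(n_i τ̄²_i + δ²*_iv)
       δ²*_iv = (θ_i + ½ Σ_j (z_ijv − γ*_iv)²)/(n_i/2 + λ_i − 1)

   until the largest absolute change is ≤ 1e−4 (max 500 iterations;
   non-convergence is an error reporting the last change).
4. Adjust y* = σ̂_v (z − γ*_iv)/δ*_iv + α̂_v + X'β̂_v, then (matching the
   study pipeline) regress age and sex out of the harmonized table once more
   (`regress_age_sex_after=False` skips this for method-level analysis).

Every site needs n_i ≥ 2 (within-site variance). The implementation is
verified to ≤ 1e−6 per entry against an independently coded, loop-based
reference in the test suite, and was cross-checked during development against
an established R implementation (agreement ~2e−6, the residual difference
coming from its relative- rather than absolute-change convergence rule).

Note the published adjustment line renders δ* ambiguously (as a product, with
σ̂ absent); the standard (z − γ*)/δ* form rescaled by σ̂_v is implemented.
The method is sometimes described as a mixed-effects regression; the printed
equations are the standard fixed-effect location/scale model and that is what
is implemented.

## Effect sizes

Hedges' g = (M_control − M_patient)/SD_pooled with the (n−1)-weighted pooled
SD; positive g = patient hypoconnectivity. The small-sample correction
J = 1 − 3/(4(n1+n2−2) − 1) is off by default (the printed formula carries no
correction, the consortium samples are large, and percent change is invariant
to a common factor); a flag enables it, cross-checked against pingouin.
Percent change is 100(g_method − g_original)/|g_original|, full precision
internally, rounded half-away-from-zero to one decimal only at the reporting
layer. For a negative g_original (not exercised by the published tables) the
sign tracks the raw difference.

## The synthetic-cohort generator

`simulate_features` draws cohorts directly from the location/scale model on
the Fisher-z scale: α_v ~ N(0.25, 0.15²) (typical z-FC levels),
β_age ~ N(0, 0.002²) per year, β_sex ~ N(0, 0.02²), additive site effects
γ_iv ~ N(Γ_i, τ²) around common per-site offsets Γ_i ~ N(0, site_sd²)
(defaults site_sd = 0.1, τ = 0.05 — site offsets about half the
between-subject noise SD, the regime where harmonization matters),
multiplicative effects δ_iv from a unit-mean inverse gamma (default fixed at
1), and noise ε ~ N(0, 0.2) (a realistic between-subject SD of z-FC). The
diagnosis effect is given in within-group SD units (default d = 0.5, medium)
and applied as patient hypoconnectivity on designated signal features.
Phenotypes are drawn per site (age normal with per-site means, sex and
diagnosis Bernoulli). Random streams are split per conceptual draw
(phenotypes / parameters / noise) via seed sequences, so outputs are
bit-reproducible and changing one block does not perturb the others. The
default desk scale is 4 sites, n_i ∈ {40, 60}, R = 20 (V = 190): large enough
for EB shrinkage to be meaningful, small enough for sub-second tests.
`bsnip_like_config()` mirrors a published 4-site schizophrenia consortium's
demography (n = 188/52/143/129, patient fractions 0.594–0.713, site age
means 33.9–39.6).

What the generator does *not* emulate: BOLD autocorrelation and any
time-series physics (the methods consume z-scale features, so noise is
Gaussian on that scale), heavy-tailed or heteroscedastic measurement error,
site-by-covariate interactions, and correlated features. Passing tests
demonstrate correctness of the estimators under their own generative model,
not performance on real scanner data. `simulate_timeseries` separately
provides multivariate-normal ROI series with a target correlation for
end-to-end FC-computation tests.

## The cross-method comparison on imbalanced cohorts

`ordering_replicates` re-simulates a cohort per replicate (site effects and
phenotypes redrawn), harmonizes, and records g and the raw group contrast per
method on the signal feature. Two opposing forces govern the outcome:
full-mode GLM removes per-feature site means, which both deflates the pooled
SD (raising g) and absorbs part of the group contrast under diagnosis
imbalance (the contrast shrinks by the factor E_HC[p] + E_P[1−p] ≈ 0.99 for
the consortium-like fractions); SWD removes only the common across-feature
site offset, leaving per-feature site deviations (τ) in place. Consequently
g_SWD reliably exceeds g_original when common site offsets are material, and
GLM's contrast absorption is detectable as a paired difference of raw group
contrasts, but the strict three-way ordering g_SWD ≥ g_original ≥ g_GLM holds
only in a small minority of replicates under this generative family: whenever
site-effect variance is large enough for SWD to beat the original, removing
it per-feature helps GLM even more. The acceptance suite states the ordering
at a 90% replicate frequency and is left failing by design rather than
tuning the generator away from its documented conditions; the measured
fraction is reported by `scripts/acceptance.py` as
`headline_ordering_fraction`.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`; rank-deficient designs are rejected up front.
- Pearson correlations are clipped to [−1, 1] and symmetrized against
  floating-point spill; zero-variance regions are an error naming the region.
- SWD site means use plain `mean` over the site block; "exact" statements
  hold to 1e−12.
- ComBat convergence: absolute change ≤ 1e−4, max 500 iterations; typical
  cohorts converge in < 10.
- Readers reject duplicate subjects, unknown diagnosis/sex labels (naming the
  row), missing age/sex, non-numeric cells (with row/column), and T < 3 time
  series; feature tables round-trip at 15 significant digits.
- T = 2 time series may be *generated* (toy draws) but are rejected by
  `compute_fc` and the reader, where the Pearson precondition actually binds.

## Known limitations

- Only linear age terms; no mixed-effects or nonlinear covariate models.
- ComBat here is the parametric variant only (no nonparametric priors,
  ComBat-GAM or CovBat).
- Effect sizes are point estimates; no confidence intervals or permutation
  inference.
- The ABIDE-scale 15-site setting is representable in the generator but the
  shipped presets are 4-site.
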