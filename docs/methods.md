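# Methods

This note documents the statistical procedures the package implements,
the choices made where conventions differ, and what the synthetic-data
tests do and do not establish.

## Design-weighted estimation

Prevalence is the Hajek ratio estimator p̂ = Σwᵢyᵢ/Σwᵢ.  Its variance uses
Taylor linearization of the ratio, with the cluster (primary sampling
unit) totals of the influence values zᵢ = wᵢ(yᵢ − p̂)/Σw aggregated within
strata: V = Σₕ nₕ/(nₕ−1) Σ_c (z_hc − z̄ₕ)².  Domain estimates keep all
clusters in the variance computation (clusters without domain members
contribute zero totals), the standard survey-domain convention.

Confidence intervals are symmetric on the logit scale and back-transformed,
which keeps them inside [0, 1]; the reference distribution is Student-t on
(number of clusters − number of strata) degrees of freedom.  For
unit-weight data reconstructed from published aggregate tables (each record
its own pseudo-cluster), this reduces to the familiar binomial/SRS interval
— which is how the published per-wave CIs are re-derived.

A stratum containing a single sampled cluster contributes zero
between-cluster variance and logs a warning ("certainty unit"), the usual
survey-software fallback that avoids an undefined variance.

### Chi-square screening

Three methods are available.  `pearson` is the classical statistic on the
weighted R×2 table (exact textbook value under unit weights).  The
Rao-Scott corrections estimate the design covariance of the cell
proportions by the same cluster linearization, form the generalized
design effects (eigenvalues of V₀⁻¹V on the contrast space of the
independence hypothesis), and divide the Pearson statistic by their mean
(first order) or additionally by (1 + CV²) with matching Satterthwaite
degrees of freedom (second order, the default).  Under a simulated
clustered null with a cluster-level factor, the second-order test rejects
at ≈5% while the uncorrected Pearson test rejects at ≈40%; this
calibration is asserted in the test suite over 1,000 replicates.

## Kitagawa decomposition

Both components use midpoint (two-wave average) weighting:
ΔY = Σⱼ Δωⱼ·ȳⱼ + Σⱼ ω̄ⱼ·Δyⱼ.  Midpoint weighting is the unique symmetric
variant with no interaction remainder, so additivity holds to machine
precision and is enforced as a property test on randomized inputs, along
with antisymmetry under wave exchange, invariance to zero-share groups,
and scale invariance.

Component shares are reported relative to the *signed* total change: a
component opposing the total appears as a negative percentage, and the two
shares always sum to 100.

A group absent from one wave enters with share 0 and prevalence defined as
0 (with a logged warning) so both waves always cover a common group set.

### Regression refinement of the behavioral component

Within each wave, subgroup prevalences yⱼ are regressed (WLS, weighted by
group share) on a numeric score Xⱼ of an auxiliary covariate — the
group-level weighted mean of ordinal category ranks 0, 1, 2, … by default,
with user-supplied scores allowed since no canonical coding exists.
Writing the fit as yⱼ = a + bXⱼ + eⱼ, the midpoint product rule gives the
exact four-term split

    Δyⱼ = Δa + b̄·ΔXⱼ + X̄ⱼ·Δb + Δeⱼ,

whose terms, scaled by ω̄ⱼ, refine the group's behavioral contribution
into an intercept shift common to all groups, a within-group improvement
in the covariate itself, a change in the covariate's gradient, and a
residual.  When the covariate's group-level score does not move between
waves the second term vanishes and the split reduces to the three-term
intercept/slope/residual form.  The identity holds by construction for any
regression weights because the residual is defined to close it; the
refinement-consistency property (terms sum to the behavioral term per
group, 1e-10) is asserted on simulated data.

## Two-level random-intercept logistic regression

The marginal likelihood Π_c ∫ Π_i p(yᵢ|β,u) φ(u; 0, σ²ᵤ) du is maximized
over (β, log σᵤ).  Numerical choices:

* **Adaptive Gauss-Hermite quadrature.**  Each cluster's integrand mode is
  located by vectorized Newton steps (all clusters simultaneously, warm-
  started between likelihood evaluations); nodes are centered at the mode
  and scaled by the curvature.  7 nodes by default: on toy fixtures the
  log-likelihood moves by < 1e-4 between 7 and 15 nodes, and at 15 nodes
  it matches a 10,000-point trapezoid integration to better than 1e-6.
  Plain (non-adaptive) quadrature was not used because its accuracy decays
  with cluster size.
* **Log-scale variance.**  Optimizing log σᵤ keeps the variance
  non-negative; the Wald CI is formed on the log scale and back-
  transformed, giving the asymmetric interval shape conventional for
  variance components.  A fitted σᵤ at the numerical floor (1e-4) is
  reported as variance 0.
* **Initialization** from an ordinary logistic GLM fit (statsmodels) and
  σᵤ = 0.5; L-BFGS-B with relative tolerance 1e-8.  Non-convergence is
  flagged on the result, not raised; |β| > 15 triggers a separation
  warning.
* **Standard errors** from a central-difference Hessian of the negative
  log-likelihood at the optimum.
* **AIC** counts k = fixed effects + 1 variance parameter (the null model
  therefore has k = 2, which reproduces the published null-model AIC from
  its log-likelihood exactly).
* **Sampling weights** (optional) enter as a pseudo-likelihood with
  level-1 weights rescaled to sum to the cluster size ("method A").  The
  default is the unweighted ML fit; both are available because survey
  practice is split on weighting multilevel models, and the two are
  reported distinctly.

Correctness is established three ways: brute-force numerical integration
of the marginal likelihood on small instances (≤5 clusters, 1e-6); the
σᵤ = 0 collapse to ordinary logistic regression (coefficient agreement
1e-3); and an independent implementation (lme4's `glmer`, adaptive
quadrature, called through Rscript) on a moderate dataset.

ICC uses the latent-threshold convention σ²ᵤ/(σ²ᵤ + π²/3) for the logit
link.  PCV is (V_null − V_model)/V_null relative to the null model of the
same sample.

## Synthetic data generator

The generator emulates the structure the estimators assume: strata defined
by region × residence; a fixed number of clusters per stratum with
Poisson-perturbed sizes (minimum 1, since real survey clusters vary);
respondent covariates drawn from wave- (optionally stratum-) specific
category distributions; outcomes from the random-intercept logistic model;
and weights equal to inverse stratum selection probabilities, normalized
to mean 1 per wave (the relative-weight convention of DHS-style surveys).
The random stream is split hierarchically (wave → stratum → cluster) so
enlarging a design leaves existing clusters' data unchanged.

Covariates are drawn independently of each other within a respondent
unless a per-stratum table is supplied — published survey reports print
marginal distributions only, so any joint structure would be an invention;
the preset's joint distribution is a product of marginals *by declaration*.

`preset_haiti_margins()` reproduces the published education and age
compositions per wave exactly and calibrates the intercepts and group
effects — by deterministic fixed-point iteration under the latent-normal
mixture — so the model-implied education- and age-specific prevalences of
the first wave and each wave's overall prevalence match the published
margins.  A single additive contrast set cannot match all three waves'
shifting group contrasts simultaneously, so later waves keep the
first-wave contrasts and re-solve only their intercepts; group-specific
prevalences in later waves are therefore approximate.  The default scale —
18 strata × 17 clusters × mean size 28, i.e. ~306 clusters and ~8,600
women per wave with cluster SD 0.86 (σ² ≈ 0.74) — mirrors the order of
magnitude of the real surveys and the published null-model cluster
variance.

**What passing tests show.**  Parameter recovery (≥90% CI coverage,
< 10% mean bias over 100 replicates) and the calibration checks establish
that the estimators are correct *under the assumed data-generating
process*.  Real survey data add features the generator omits —
nonresponse, joint covariate dependence, within-cluster covariate
correlation, informative weighting — so these tests validate the
machinery, not the substantive estimates one would obtain on real
microdata.

## Data conventions and edge cases

* CSV is the interchange format; a YAML schema declares each covariate's
  categories, reference level and level (individual/community).  Category
  matching is exact and case-sensitive; any malformed value is a named
  error, never a silently dropped row.  Missing covariate cells are
  rejected by default; an explicit allow-missing flag performs
  complete-case filtering with a logged count.
* Published percentage tables are consumed as-is except that group shares
  are renormalized to sum exactly to 1 (printed percentages carry up to
  0.1 rounding slack per column).
* Wave labels are opaque strings ordered by configuration, not parsed as
  dates.

## Known limitations

* Single-factor decomposition only; no simultaneous multivariate
  (Das Gupta / Oaxaca-Blinder) decomposition.
* Two-level models only: no random slopes, cross-classification, or
  three-level nesting.
* The Rao-Scott second-order statistic is referred to a chi-square with
  Satterthwaite degrees of freedom; an F-reference variant (as in some
  survey software) is not provided, so printed p-values from other
  software may differ slightly in small samples.
* Published adjusted odds-ratio tables cannot be reproduced without the
  registration-gated microdata; the multilevel layer is validated by the
  oracle and recovery tests above instead.
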