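# Methods

`codrange` re-creates, as a tested pipeline, a hierarchical Bayesian
analysis of resource-driven range expansion in a demersal fish stock
surveyed by a decade of bottom-trawl stations. This note documents the
models, the synthetic data they are exercised on, the numerical choices,
and the known limitations — in that order.

## Analysis variables

**Stomach fullness (CSF).** For each sampled fish, stomach content weight
(g) divided by body length (cm) cubed, times 10^4. The index is
dimensionless and length-standardized; doubling length at fixed content
divides it by 8. Stomachs are routinely empty, so the modelled response is
`log(CSF + 0.02)`: the offset keeps zeros finite and the log is the
Box–Cox-preferred transform for this kind of positive, right-skewed index.
`boxcox_select` exposes the profile-log-likelihood machinery (grid default
λ ∈ {−2, −1.9, …, 2}, offset fixed at 0.02 rather than jointly estimated)
so the choice can be re-audited on any dataset; on simulated lognormal
values it selects λ ≈ 0 and on normal values λ ≈ 1. "log" is the natural
logarithm throughout; the choice only shifts likelihoods by constants.

**Occupancy (CO).** The proportion of trawl sets in a subregion-year in
which fish of a given age class were caught, kept as counts
(`n_present` of `n_sets`) so the binomial likelihood is exact. Cells with
no sets are absent, not zero-filled.

**Standardized temperature.** Bottom-temperature casts are adjusted to a
common reference (200 m depth, day-of-year 246, i.e. 3 September) by an
additive regression-spline model: temperature on subregion-year cell
means plus cubic B-spline smooths of depth (5 basis functions) and
day-of-year (4 basis functions), fitted by OLS. Each cast's standardized
value is its observed temperature minus the fitted smooth adjustment
relative to the reference point; cast-level residual variation is
deliberately retained so the downstream temperature trend regression sees
realistic within-cell spread. A cast already at the reference point is
returned unchanged; adding a constant to all temperatures shifts all
standardized values by that constant. If depth (or date) has no
variation, that smooth is dropped and the drop is logged. The true
adjustment model behind the published analysis is not fully specified
anywhere we could implement from; this spline adjustment is an explicit
stand-in with the stated properties.

**Grid subregions.** As a design-free alternative to predefined
subregions, `bin_grid_subregions` bins coordinates into an equal-interval
lat/lon grid (half-open intervals, upper boundary in the last bin) over a
configurable bounding box (default 68–82°N, 14–57°E).

## Trend models (`hier_glmm`)

For response `Y_ijk` (age i, subregion j, year k):

    f(mu_ijk | a_ij, b_ij) = alpha + beta * Year_k + a_ij + b_ij * Year_k

with f = logit and a binomial likelihood for occupancy, f = identity and a
Gaussian likelihood for transformed stomach fullness, and Year_k = year −
2004 so the intercept is the level at the start of the series. Random
intercepts a and slopes b are zero-mean normal with free standard
deviations; the grouping runs over a ladder — none, age (10 levels),
subregion (11), age + subregion (additive, separate variances per
component), or the full age-by-subregion interaction (up to 110 cells).
Random slopes without random intercepts are not representable, matching
the ladder's design. Intercepts and slopes within a grouping are
independent (the written model specifies only the two variances); this is
deliberate — the common correlated-effects default is the documented
alternative, not the implementation.

Priors: normal(0, 10) on the intercept, normal(0, 2.5) on the year
coefficient — optionally autoscaled (intercept sd × sd(y), coefficient
sd × sd(y)/sd(year) for the Gaussian model; coefficient sd / sd(year) for
the binomial) — and half-Normal(0, 2.5) on every standard deviation
(unstated in the source analysis; chosen weakly informative on the
coefficient scale).

**Sampler.** The package bundles its own blocked MCMC (no external
probabilistic-programming dependency), vectorized across chains:

* Gaussian responses: exact conjugate Gibbs draws for the fixed-effect
  pair and for every (a_g, b_g) block, via per-cell sufficient statistics.
* Binomial responses: independence Metropolis–Hastings per block with a
  Laplace proposal — a Newton mode/Hessian search started from zero, so
  the proposal depends only on the conditioning state, as validity of the
  independence sampler requires. Acceptance rates are typically 0.8–0.95;
  a block stuck below 5% acceptance raises rather than silently degrading.
* Standard deviations: stepping-out slice sampling on log σ.
* A recentering move — the exact Gibbs draw along the likelihood-invariant
  translation (alpha + d, a_g − d), and its slope analogue — removes the
  slow random-walk between fixed effects and random-effect means that
  plain blocked updates would exhibit.

Defaults mirror the published protocol: 4 chains × 2,000 iterations with
1,000 discarded as burn-in and no thinning. On the default synthetic
survey this fit takes ~15–20 s on one CPU and reaches max split R-hat
≈ 1.001 and min ESS ≳ 2,000 over the focal parameters (fixed effects and
variance components).

**Diagnostics.** Split-chain R-hat (between/within variance on
half-chains; identical constant chains return 1 by convention) and
multi-chain autocorrelation ESS with Geyer initial-monotone truncation
(constant chains report 0 with a warning, values capped at the draw
count). Both are cross-checked against arviz in the test suite.

**Model comparison.** WAIC and PSIS-LOO from the pointwise
log-likelihood: binomial cells are the observation unit for occupancy,
individual fish for stomach fullness. PSIS smooths the top 20% of each
observation's importance ratios with a generalized-Pareto fit (Zhang &
Stephens estimator, weak prior toward k = 0.5), truncates at the raw
maximum, and flags k > 0.7. Fewer than 100 draws falls back to unsmoothed
importance sampling with a warning. Ranking is by elpd_loo, ties broken by
fewer effective parameters.

## Correlation stage (`param_correlation`)

The question "did subregions with more initial food expand faster?" is
answered inside the MCMC. Both responses get fully independent fixed-effect
coefficients per age-by-subregion cell (normal(0, 10) priors, no partial
pooling — matching the displayed model of the source analysis; the
hierarchical alternative lives in the trend-model ladder only), with
independent error terms:

    E[log(CSF_ijk + 0.02)] = alpha_CSF,ij + beta_CSF,ij * Year_k
    logit[p_CO,ijk]        = alpha_CO,ij  + beta_CO,ij  * Year_k

For each retained draw, the Pearson correlation of (alpha_CSF,ij,
beta_CO,ij) across the J subregions at fixed age i is computed; the
resulting chain of correlations is summarized by its mean and central 95%
interval. Only this per-draw construction propagates the estimation
uncertainty of the intercepts and slopes into the correlation; correlating
posterior means would not. Draws where either vector is constant across
subregions are excluded with explicit accounting. Rank correlation is
available as a manual alternative by transforming the draws; Pearson is
the default and the reported quantity.

Temperature enters the same machinery per subregion-year (casts carry no
age information) and its coefficients are broadcast across ages — the
age-indexed notation for temperature in the source is interpreted this
way, not asserted as the authors' intent.

Sampling: Gaussian cells by conjugate Gibbs given a shared residual sd
(slice-sampled); binomial cells by independence MH with a fixed
multivariate-t proposal (df 7, Laplace covariance inflated 1.3×) computed
once per cell, since cells share no parameters and each cell's target is
fixed. Protocol defaults: 3 chains × 20,000 iterations, first 10,000
discarded, keeping every 5th — exactly 6,000 retained draws. On the
default survey this takes ~10 s, acceptance ≈ 0.8, max R-hat ≈ 1.001,
min ESS ≳ 4,000 across all cell coefficients. A single-cell posterior
was verified against brute-force 2-D grid integration (means and sds
agree to ~3 decimals); the test suite keeps that check.

## Synthetic survey generator (`survey_synth`)

The generator emulates the survey the models assume, with known truth:

* 11 subregions, ages 1–10 (10 = pooled 10+), years 2004–2013; per-year
  station counts fixed at (316, 580, 316, 316, 315, 315, 310, 316, 316,
  316) — within the observed 310–580 range, extremes in the years they
  occurred, 3,416 sets in total. Sets are allocated equally among
  subregions (allocation is configurable; the true allocation is not
  recorded in our sources).
* Occupancy: per (set, age) Bernoulli at the cell's logit-linear truth.
  Random effects decompose into age, subregion and age-by-subregion
  components with configurable sds (defaults: intercept components
  0.8/0.7/0.7, slope components 0.05/0.10/0.10 on the logit scale around
  alpha = −0.5, beta = 0.15/yr) — producing cells from near-absent to
  near-saturated, like the survey the design imitates.
* Stomach fullness: one fish per present age per set (configurable).
  Fish-level log(CSF + 0.02) = cell line + N(0, 0.6); lengths from
  age-specific normals (a gadoid growth curve, sd 4 cm) make the
  length-standardization non-trivial; weights are back-solved from the
  index and truncated at zero (truncation is rare, < 1% at defaults, and
  is a documented small bias at extreme parameter settings). A 10% point
  mass of empty stomachs exercises the +0.02 offset; it shifts cell
  intercepts by a near-constant and scales slopes by 0.9, leaving
  cross-subregion correlations unchanged.
* The expansion mechanism: the subregion-main and interaction components
  of (CSF intercept, occupancy slope) are drawn bivariate-normal with
  correlation `rho_init_expansion` (default 0.8, the strong-signal
  regime). When each member's two component sds are proportional (as in
  the defaults) the summed effects have exactly that correlation;
  otherwise it attenuates by a closed form exposed as
  `TrueParameters.population_init_expansion_correlation`.
* Temperature: per-subregion linear trends (defaults spanning −0.05 to
  +0.08 °C/yr — divergent cooling-to-warming, intercepts 0–4 °C), a
  shared subregion-by-year anomaly (sd 0.4 °C) representing interannual
  variability, and per-cast noise (sd 0.3 °C). The year anomaly matters:
  without it, ten yearly means pin the fitted trend almost exactly and
  the temperature side of the correlation stage would look unrealistically
  certain. Optional depth/date effects (default 0) exercise the
  standardization stage.
* Reproducibility: one master seed; every stochastic component draws from
  a named `SeedSequence.spawn` stream, so identical configurations are
  byte-identical on disk.

What the generator does *not* emulate: spatial coordinates and
autocorrelation within subregions, shelf-break heterogeneity, multispecies
structure, prey dynamics (so no feedback from fish density to stomach
fullness), age-length misclassification, and survey-effort gaps. Passing
recovery tests therefore show that the estimators work when the model's
assumed structure is the data-generating structure — not that the
assumptions hold for any real survey.

## Problem sizes used by the test and acceptance runs

Unit tests run reduced surveys (3–6 subregions, 2–3 ages, 60–220 sets per
year) chosen to finish in seconds while leaving the checked quantities
well-identified. The acceptance suite uses the full default survey
(11 × 10 × 10 years, 3,416 sets) for the convergence bounds, and ten
survey-scale replicates with a proportionally reduced correlation-sampler
budget (3 × 5,000 iterations, 2,500 burn-in, thin 5) for the recovery
checks. The acceptance script runs the full published protocol
(4 × 2,000/1,000; 3 × 20,000/10,000/5).

## Known limitations

* **Attenuation of the correlation estimator at the occupancy boundary.**
  Age-by-subregion cells whose occupancy sits at 0 or 1 for most years
  carry almost no information about their slope; those coefficients are
  prior-dominated and the per-draw correlation concentrates below the
  realized truth. On ten survey-scale replicates at rho = 0.8, the 95% CI
  covered the realized per-age truth in ~60% of age-replicates (posterior
  means e.g. 0.68 against a realized 0.94), while the positive-signal
  structure itself was recovered in 96%. The effect is a property of the
  estimator — verified by the grid-integration check above and by its
  disappearance in the informative-cell limit — and it should temper any
  quantitative reading of such correlations near occupancy boundaries.
  The corresponding acceptance assertion is intentionally left failing as
  a faithful record of this behavior.
* **Per-age null correlations are not zero at J = 11.** With eleven
  subregions the realized correlation between a fixed temperature-slope
  vector and any age's realized occupancy slopes scatters with sd
  ≈ 1/√(J−1) ≈ 0.32 even when the generating processes are independent. A
  faithful estimator tracks these realized values, so single-dataset
  per-age CIs can legitimately exclude zero; only the pooled (across-age,
  or across-replicate) null is stable. The per-age universal-containment
  acceptance assertion is likewise left failing, with the pooled check
  green.
* The Gaussian model for transformed CSF ignores the two-part
  (empty/non-empty) structure; at the default 10% empty mass this biases
  intercepts by a near-constant and slopes by a factor 0.9 and leaves
  correlations intact, but a heavily zero-inflated dataset would warrant
  an explicit hurdle model.
* The additive random-effects decomposition in the truth generator is
  richer than any single fitted model; exchangeable-cell fits absorb the
  main effects into the cell effects, so fixed-effect recovery tests use
  interaction-only truths.
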