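# Methods

## Model

The package implements a jointly estimated two-part ("hurdle") model for
areal report counts `Y_it` over census tracts `i = 1…n` and periods
`t = 1…T`:

* reporting part: `Y_it ~ Binomial(n_i, P_it)`, `logit(P_it) = β₀ + x_iᵀβ_B + η_i + S_i + τ_t`,
  with `n_i` the tract population at risk;
* count part: `Y_it ~ Poisson(θ_it)`, `log(θ_it) = β₀' + x_iᵀβ_P + α(η_i + S_i + τ_t)`,
  applied to **all** observations (no zero-truncation: settings of interest
  have very few all-zero tracts).

Both parts are evaluated on the same observed count and share the latent
components; the joint log-likelihood is the sum of the two observation terms
plus the latent Gaussian log-densities. This "stacked likelihood with shared
latents" construction is the standard way to estimate the two parts together
in the latent-Gaussian tradition. The sharing factor α defaults to 1 and is
held fixed. Fixed-effect vectors are separate per part (this nests the
shared-coefficient case).

Latent structure:

* `η_i ~ N(0, σ²_η)` i.i.d. — non-spatial tract heterogeneity;
* `τ_t` — first-order random walk with innovation variance σ²_τ, constrained
  to sum to zero (the density is evaluated on the T−1 increments; the
  constraint is imposed structurally). The sum-to-zero constraint, together
  with centring η during inference, resolves the intercept confounding that
  any additive latent structure otherwise has;
* `S ~ MVN(0, Σ)` with Matérn covariance
  `Σ_ij = σ²/(2^(ν−1)Γ(ν)) (κd_ij)^ν K_ν(κd_ij)` over Euclidean distances of
  projected (metre-based) tract centroids. The range `ρ = √(8ν)/κ` is the
  distance at which correlation ≈ 0.1. The field is evaluated exactly at the
  centroids (dense covariance + Cholesky with escalating diagonal jitter);
  no mesh/SPDE approximation is used — exact and fast below a few hundred
  tracts. Smoothness ν is fixed at 1 by default (the customary default when
  ν is not identifiable from areal data) and exposed in configuration.

### Known structural consequences of the composite likelihood

Two properties follow from using the same `Y_it` in both parts; they are
properties of the model class, not implementation artifacts:

1. **Population-scale tension.** The binomial part models a proportion
   (`Y/n_i`), the Poisson part a count, and neither predictor carries
   `log n_i`; the shared latent therefore absorbs about half the per-tract
   `log n_i` spread. This inflates the fitted σ²_η and widens tract-level
   coefficient posteriors relative to a single-likelihood fit.
2. **Double-counting overconfidence.** Each latent value is informed by the
   same data twice, so per-tract η posteriors are narrower than sampling
   variation warrants. Exceedance maps built on `exp(S+η)` consequently
   over-flag isolated tracts; maps built on the spatially structured
   component `exp(S)` are protected by the Matérn prior, which only rewards
   spatially coherent patterns.

For this reason the library default for relative-risk surfaces is the
covariate-adjusted residual risk `RR_i = exp(S_i + η_i)` (a component switch
selects `exp(S)` only, or adds the centred fixed-effect contribution for a
full-risk map), while the package's own calibration and detection studies
(below) evaluate the spatial component, which is the question the
80%/20% exceedance rule is designed to answer.

## Covariates and coding

Thirteen tract-level census covariates enter both parts, constant over time
(single-census measurements):

* **deprivation index** — first principal component of the six standardised
  indicators (unemployment, manual workers, temporary workers, without
  compulsory schooling, the same for ages 16–29, without internet),
  sign-oriented so that higher = more deprived. This is the standard MEDEA
  small-area construction; the exact 2011 index weights are not public, so
  the PCA construction stands in for them. Coded as one Q4–Q5 dummy
  (reference Q1–Q3).
* **unemployment** — four quintile dummies Q2…Q5 (reference Q1).
* **without compulsory schooling** — Q4–Q5 dummy; **young variant** — Q1–Q3
  dummy (reference Q4–Q5).
* remaining covariates (housing <45 m², housing 45–60 m², foreign %,
  African/South-American/Asian %, manual %, temporary %, no-internet %) enter
  as raw percentages.

Quintile boundaries are the 20/40/60/80th percentiles of the tract
distribution, left-closed, ties to the lower quintile (chosen for determinism;
this makes the coding invariant to strictly monotone transformations). The
design matrix has 16 columns forming 13 coefficient terms; the column order
is fixed and documented in `covariates.DESIGN_COLUMNS`.

## Priors

Nothing in the applied literature this model family comes from pins the
priors, so weakly-informative defaults are used and fully exposed:

| parameter | prior | default |
|---|---|---|
| intercepts, coefficients (standardised-covariate scale) | Normal(0, sd²) | sd = 5 |
| σ_η, σ_τ, σ (spatial) | half-Normal(scale) | scale = 1 |
| ρ (range) | log-Normal, median = 20% of domain diameter | sdlog = 0.7 |
| ν | fixed | 1 |

Covariates are standardised internally (coefficients are mapped back to the
raw scale in the reported draws), so the coefficient prior has a consistent
meaning across covariates with very different scales.

## Inference

Applied work with this model family typically uses INLA; this package
instead targets the same posterior with its own documented MCMC scheme
(equivalence of target density, not algorithm, is the contract):

* **HMC block** (leapfrog, randomised step count in [L/2, L], dual-averaging
  step size, diagonal mass matrix estimated in a warmup window):
  coefficients, whitened latents, and the three log standard deviations,
  all with analytic gradients. The parameterisation is non-centred
  (`η = σ_η z`, `S = σ L(ρ) z`, `τ = σ_τ·RW1(z)` centred), which avoids the
  small-variance funnel.
* **Metropolis on log ρ** (the gradient would require differentiating a
  Cholesky factor), with the whitened field held fixed, plus an interweaved
  move that holds **S itself** fixed and rotates the whitened coordinates
  (`z' = L'⁻¹ L z`).
* **Interweaved rescaling moves** for each scale: propose a new σ while the
  latent values stay fixed (`z' = z·σ/σ'`), so only prior and Jacobian terms
  enter. Non-centred updates freeze when the data pin the latents tightly;
  these ancillarity–sufficiency moves restore mixing in exactly that regime.
* Latent scales are initialised with most mass on the spatial component
  (σ init 0.5 vs 0.05 for η): if tract-level structure is spatially
  coherent the chain finds the S-mode directly, and if not, σ² shrinks
  during warmup. Starting with a large IID scale can trap η in a mode that
  also soaks up spatial signal (the well-known structured/unstructured
  identifiability trade-off).

Chains run sequentially from seeds spawned off the user seed; every fit is
bit-reproducible given (data, config, seed). Split-R̂ is computed in-house
(with the zero-variance convention R̂ = 1); bulk ESS comes from arviz. A
fitted model warns when any monitored R̂ exceeds 1.05.

Defaults (2 chains, 500 warmup + 500 draws, ≤48 leapfrog steps) fit an
80-tract × 7-period panel in well under a minute on one CPU.

## Synthetic data: what it emulates, and what it does not

`synthetic` generates the study conditions end to end:

* **geography** — Voronoi tessellation of uniform points in a square extent
  (default 10 km), mirrored across the edges so cells are exactly clipped;
  contiguous irregular tracts resembling census geography. Populations
  log-uniform in [500, 3000] (the realistic Spanish tract range; only the
  relative scale matters).
* **covariates** — the six deprivation indicators share one latent factor
  (loading 0.7) so the composite index is meaningful; marginal means/SDs sit
  near published small-area descriptives (e.g. unemployment 24.46 (9.47),
  manual workers 52.24 (17.42), no-internet 33.38 (9.73)); the two schooling
  marginals are plausible choices (26 (7) and 15 (5)) because the published
  table reports only quintile-group summaries for them. Foreign-origin
  subgroups are a Dirichlet split of the overall foreign percentage, which
  enforces their sum constraint by construction. Percentages are clipped to
  [0, 100].
* **latent fields** — one Matérn draw at the centroids (default σ² = 0.1,
  ν = 1, ρ = 2 km), i.i.d. η (default variance 0.05), RW1 τ (default
  innovation variance 0.02), all exactly zero when the variance is zero.
* **observations** — two modes. `"hurdle"` (default): a tract-period gate
  `g ~ Bernoulli(logistic(ℓ₁))` followed by `Y ~ Poisson(exp(ℓ₂))` when the
  gate opens — a literal gate-then-count selection process that produces
  excess zeros relative to a matched Poisson. `"binomial"`: counts drawn
  directly from the reporting part's own law `Binomial(n_i, logistic(ℓ₁))`.
  Default coefficients are published-scale log odds-ratios in the reporting
  part (deprivation Q4–Q5 OR 0.573, housing45 0.894/%, foreign 1.028/%, …)
  with a gate intercept giving open-gate probability ≈ 0.7–0.9 (few zero
  tracts) and count intercept log 5; the count part carries no covariate
  effects by default — covariates drive reporting propensity, not incident
  intensity. A configurable fraction of tract-periods (default 5%) is
  removed completely at random to make the panel unbalanced, and a flag
  controls whether zero counts appear as explicit rows (default) or are
  absent.

The generator does **not** attempt the real joint covariate distribution,
real tract geometry, within-tract population structure, or temporal change
in covariates. Passing tests therefore demonstrate correctness of the
machinery and the model's operating characteristics under known truth — not
that the substantive conclusions transfer to any particular city's data.

## Study conditions for the verification experiments

* **Recovery** (`experiments.recovery_study`): 20 replicates at 100 tracts ×
  7 periods, `"binomial"` observation mode, deprivation-dummy log-OR set to
  log 0.573, per-person reporting intercept −5.8 (≈ 2 reports per 1000
  population per period), modest latent variances (σ²_η = 0.02, σ²_τ = 0.01,
  σ² = 0.05). The binomial mode is used because under gate-then-count data
  the reporting part's estimand for a covariate is `(1−p_gate)β_B + β_P`,
  not `β_B` — no correct fit of the stated model recovers the coefficient in
  that mode, whereas the binomial law is exactly the reporting part's model.
  Reported: 95% interval coverage and the Monte-Carlo bias of the posterior
  mean across replicates. The per-replicate absolute error is dominated by
  sampling variance (the deliberately collinear deprivation indicators give
  the dummy an MLE standard error ≈ 0.11 at this size), so bias — the
  systematic component — is the meaningful accuracy measure.
* **GLM limit** (`glm_limit_study`): 200 tracts simulated with all latent
  variances zero, fitted with latent components disabled; posterior means of
  both parts must sit within 3 posterior SDs of the statsmodels IRLS fits.
* **Null calibration** (`null_calibration_study`): 3 replicates at 60
  tracts, flat latent truth (σ² = 1e−8, η off), gate ≈ 0.9, count intercept
  log 5; fraction of tracts labelled hotspot from `exp(S)` exceedance.
* **Detection** (`detection_study`): 3 replicates at 100 tracts, flat
  background with one disc (radius 30% of the extent) where S is shifted by
  +log 2, count intercept log 40 ("sufficient counts": the field needs
  volume to localise a sharp-edged disc with a smooth stationary
  covariance); fraction of in-region tracts with PRP > 0.8, averaged over
  replicates. Boundary tracts of a sharp disc are intrinsically smoothed
  toward the background, so per-replicate fractions fluctuate (~0.75–1.0);
  averaging reflects the operating characteristic rather than one
  geometry's luck.

Replication counts and sampler settings (2 chains, 400–600 warmup, 300–400
draws) are the package's standard study sizes, chosen so the full suite runs
on a laptop-class single core in minutes.

## Numerical choices and edge cases

* Binomial log-pmf via `y·ℓ − n·softplus(ℓ)` with gammaln binomial
  coefficients — stable for |ℓ| up to ~700.
* Matérn at d = 0 returns σ² exactly; covariance matrices get diagonal
  jitter 1e−8·σ², escalated ×10 up to three times before a numerical error
  is raised (coincident centroids survive via jitter).
* Zero latent variances are exact point masses (simulator emits exact
  zeros; the joint density returns −∞ for nonzero latents).
* Predictors beyond ±200 make the posterior −∞ (rejected by the sampler);
  the simulator refuses Poisson log-rates above 30 with advice to rescale.
* Quintile ties go to the lower quintile; boundary exceedance values
  (PRP exactly 0.8/0.2) are "uncertain"; exceedance uses strict "> 1", so a
  degenerate all-unit posterior yields PRP = 0 (coldspot) — the
  all-"uncertain" case is a diffuse posterior centred on 1.
* Boundary points in point-to-tract assignment go to the tract whose id is
  smallest in string order; a point outside every polygon is an error
  naming its coordinates.

## Limitations

* The composite two-likelihood construction is taken as given (it is the
  model family's defining feature); its double-counting overconfidence and
  population-scale tension are documented above rather than "fixed", since
  any fix (offsets, part-specific latents) would change the model.
* No model comparison (DIC/WAIC), no cross-validation, no INLA benchmark.
* ν is fixed; anisotropic or non-stationary covariances are out of scope.
* The sampler is designed for desk-scale problems (≲ a few hundred tracts);
  the dense Cholesky makes cost cubic in tract count.
* No imputation: covariates must be complete; inputs must already be in a
  projected metre-based coordinate system.
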