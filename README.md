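# hurdlemap

Spatial–temporal Bayesian hurdle modelling of police-reported domestic
violence counts at census-tract level, with exceedance-probability hotspot
mapping.

## The problem

Police-report counts of domestic violence are a selected sample of the
underlying offences: victims who report are more likely to be observed, and
the unobservables driving reporting are correlated with the unobservables
driving the offence process itself (endogenous selection). Weighting cannot
fix this, so reporting and counts are modelled **jointly** as a two-part
(hurdle) model over an unbalanced panel of census tracts *i = 1…n* observed
in annual periods *t = 1…T*:

* **Reporting part** — the count `Y_it` against the tract population at risk
  `n_i`:

  ```
  Y_it | P_it ~ Binomial(n_i, P_it)
  logit(P_it) = β₀ + x_iᵀβ_B + η_i + S(x_i) + τ_t
  ```

* **Count part** — the same count through a (non-truncated) Poisson law:

  ```
  Y_it | θ_it ~ Poisson(θ_it)
  log(θ_it)  = β₀' + x_iᵀβ_P + α·(η_i + S(x_i) + τ_t)
  ```

The two parts are estimated together and share the latent structure:
`η_i ~ N(0, σ²_η)` is unstructured tract heterogeneity, `τ_t` is a
first-order random walk over periods (sum-to-zero), and `S` is a zero-mean
Gaussian field over tract centroids with Matérn covariance

```
C(d) = σ² / (2^(ν−1) Γ(ν)) · (κd)^ν K_ν(κd),     range ρ = √(8ν)/κ,
```

where `K_ν` is the modified Bessel function of the second kind and ρ is the
distance at which spatial correlation falls to ≈ 0.1. The covariates `x_i`
are thirteen small-area census measures — a six-indicator deprivation index
(first principal component, quintile-grouped), unemployment quintiles,
housing size, foreign-origin percentages, occupational and schooling
indicators, internet access — coded with the reference-category scheme used
in the small-area deprivation literature. `exp(β)` is the odds/rate ratio
reported for each term.

Posterior exceedance probabilities `PRP_i = Pr(RR_i > 1)` of the smoothed
relative risk `RR_i = exp(S_i + η_i)` feed the Richardson interpretation
rule: PRP > 0.8 flags a hotspot, PRP < 0.2 a coldspot.

Because real police-report microdata are access-restricted, the package
ships a first-class synthetic-data module that generates small-city
geographies (Voronoi tracts), covariates with realistic marginals, latent
Matérn risk fields, and selection-biased counts — every downstream stage is
testable end to end with known ground truth.

## Worked example

```python
import hurdlemap as hm

# an 80-tract, 7-period synthetic city with published-scale covariate effects
scenario = hm.default_scenario(n_tracts=40, seed=3)
tracts, effects, panel = hm.simulate_scenario(scenario)

post = hm.fit(panel, sampler=hm.SamplerConfig(chains=2, draws=300, warmup=400), seed=1)
print(hm.summarize(post, level=0.95, part="binomial").head(3))

surface = hm.build_risk_surface(post, list(tracts.table.index))
print(surface.table["hotspot_label"].value_counts().to_dict())
```

Output from this exact snippet:

```
                  or_mean    or_low   or_high  contains_one  significant
term
intercept        0.007443  0.000860  0.024503         False         True
deprivation_q45  1.217074  0.329725  3.010625          True        False
unemployment_q2  2.629819  0.854263  6.614919          True        False
{'uncertain': 25, 'coldspot': 9, 'hotspot': 6}
```

The first table row is the reporting-part intercept on the odds scale (tiny,
as expected for per-person reporting probabilities); each further row is a
covariate's odds ratio with its 95% equal-tailed credible interval and the
interval-excludes-one significance flag. The label counts summarise the
exceedance-probability map: with only 40 tracts and moderate counts most
tracts stay "uncertain" — individual covariate effects and tract risks are
only weakly identified at this size, which is why the verification studies
use more tracts and replicates.

The same pipeline runs from the shell:

```bash
hurdlemap full --config run.yaml --seed 1 --out-dir runs/demo
```

writing the simulated data (GeoJSON + CSV), the posterior store, odds-ratio
tables at 90/95%, risk-surface layers (GeoJSON/CSV/PNG choropleth), and a
JSON run manifest.

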