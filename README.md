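# fertimap

Model-based geostatistical mapping of total and age-specific fertility
rates (TFR / ASFR) from cluster-sampled household-survey data, of the kind
collected by Demographic and Health Surveys (DHS): retrospective birth
histories recorded in century-month codes, georeferenced survey clusters
with design weights, and gridded environmental covariates.

The package is written for demographers and spatial epidemiologists who
want high-resolution fertility maps and small-area estimates from such
surveys, together with honest posterior uncertainty. Because real DHS
microdata are access-restricted, fertimap ships a seeded synthetic-data
generator that reproduces the statistical structure of the problem —
stratified two-stage clusters, birth histories driven by a latent spatial
fertility surface, smooth covariate rasters, nested admin units — so every
stage of the pipeline is testable at desk scale.

## The model

Direct estimation first: for each survey cluster the age-specific
fertility rate in five-year group *a* over the 36 months before interview
is ASFR_a = Σᵢ wᵢ bᵢₐ / Σᵢ wᵢ eᵢₐ (weighted births per woman-year of
exposure, exact integer-month arithmetic), and TFR = 5 Σₐ ASFR_a.

Cluster-level rates y(sᵢ) are then modelled with a Gaussian additive
geostatistical model

  yᵢ = β₀ + Σⱼ βⱼ Xⱼᵢ + Σₖ fₖ(Xₖᵢ) + u(sᵢ) + εᵢ

where X are standardized covariates (travel time to the nearest city,
distance to health facilities, a kriged proportion-of-Muslim-women
surface, altitude, population density), fₖ are penalized cubic-spline
smooths, u is a zero-mean Gaussian random field with Matérn correlation
(partial sill σ², range φ, smoothness ν = 1) and εᵢ ~ N(0, τ²) is the
nugget. All coefficients carry mean-zero Gaussian priors. With a Gaussian
likelihood the posterior given the hyperparameters is exactly Gaussian,
so inference is deterministic: the exact marginal likelihood is evaluated
on a grid of (σ², φ, τ², penalty) nodes and per-node Gaussian posteriors
are mixed over the normalized weights — the same target that INLA-style
deterministic Bayes computes, without an SPDE mesh. Pixel-level posterior
surfaces (mean, sd, 95% credible interval) follow from the Gaussian
conditional of the field, and are aggregated to district / zone / region /
national estimates as population-weighted means of pixel values.

## Worked example

`examples/04_fit_geostat.py` simulates a survey of 400 clusters, computes
direct cluster TFRs, and fits the spatial model:

```text
                term   mean    sd  lower95  upper95
           intercept  4.495 0.187    4.108    4.866
    travel_time_city  0.533 0.127    0.285    0.783
dist_health_facility  0.086 0.107   -0.124    0.296
         prop_muslim  0.282 0.110    0.066    0.499
            altitude  0.107 0.106   -0.101    0.316
         pop_density -0.066 0.127   -0.315    0.185
generating values: {'travel_time_city': 0.42, 'dist_health_facility': 0.17,
                    'prop_muslim': 0.37, 'altitude': 0.14, 'pop_density': -0.01,
                    'intercept': 4.5}
```

Each coefficient is a per-standard-deviation effect on the TFR scale with
its 95% credible interval; the generating values used by the simulator
are shown for comparison, and all sit inside their intervals. The other
examples cover simulation (`01`), direct rates by stratum (`02`), kriging
the proportion covariate (`03`), pixel prediction and small-area
aggregation (`05`), and the orchestrated end-to-end run (`06`). A thin
CLI mirrors the library:

```bash
fertimap run-all --out run/ --seed 1
```

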