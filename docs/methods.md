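# Methods

## Direct rate estimation

Birth histories are handled in century-month codes (CMC): every date is an
integer month, and all exposure arithmetic is exact. The estimation window
is the right-closed interval of `window_months` (default 36) calendar
months ending at, and including, the interview month. A woman contributes
exposure to age group *a* ∈ {[15,20), …, [45,50)} for every window month in
which her age in months lies in [180 + 60a, 180 + 60(a+1)); the day of the
month is unknown under the CMC convention, so group boundaries sit at exact
month multiples, lower-inclusive. Births are assigned to the mother's age
group at the birth month; births to mothers outside [15, 50) at delivery
are excluded from numerators and reported in a diagnostics tally. Weighted
group totals give ASFR_a = Σ wᵢbᵢₐ / Σ wᵢeᵢₐ and TFR = 5 Σₐ ASFR_a; a
group with zero exposure is flagged as undefined and contributes 0 to the
TFR rather than propagating NaN. The "summed ASFR" scalar reported beside
the TFR is Σₐ ASFR_a = TFR/5, the single-number ASFR convention used in
national reporting.

## Covariate handling

All rasters live on axis-aligned km grids (north-west origin, row 0
northmost). Harmonization to the common ~1 km analysis grid uses
area-weighted means when coarsening and bilinear interpolation of cell
centres when refining; nodata cells are excluded from means. Cluster-level
covariate values are buffer means — 2 km radius for urban clusters, 5 km
for rural — absorbing the positional displacement applied to survey
cluster coordinates; buffer membership is by cell centre (simple and
deterministic; partial-cell area weighting was considered and rejected as
spurious precision at 1 km resolution). Columns are standardized to mean 0,
sd 1 over the cluster sample and the constants recorded, so fitted
coefficients are per-SD effects and prediction reuses the training-time
scaling. A Pearson screen flags any covariate pair with |r| ≥ 0.7; the
library-level fit refuses such designs, while the orchestrated pipeline
drops the later-listed member of each flagged pair (logged) and proceeds,
mirroring the practice of selecting a covariate set that passes the screen.

## Matérn family and kriging

The spatial kernel everywhere is the Matérn correlation
ρ(d) = 2^(1−ν)/Γ(ν) (κd)^ν K_ν(κd) with κ = √(8ν)/φ, so the range φ is the
distance at which correlation has decayed to ≈0.13 (ν = 1). ν is fixed at 1
(the two-dimensional SPDE default); ν = 0.5 gives the exponential kernel
exp(−2d/φ) and is available for checks.

The proportion-of-Muslim-women covariate is produced by Bayesian kriging
of cluster-level proportions: a Gaussian process with mean μ₀ (the
weighted mean of the observations), Matérn covariance σ²ρ and nugget τ².
"Bayesian" means deterministic integration over an 11 × 11 × 5 log-spaced
grid of (σ², φ, τ²) nodes: each node's exact Gaussian marginal likelihood
is combined with independent log-normal priors — ln σ² ~ N(ln var(y),
1.5²), ln φ ~ N(ln 0.25L, 1.5²) with L the domain diagonal, ln τ² ~
N(ln 0.1 var(y), 2²) — and predictions mix the per-node Gaussian
conditionals over the normalized weights (mixture variance = within-node
plus between-node). The posterior mean surface is clipped to [0, 1] after
mixing; proportions are treated on the identity scale (a logit link is a
possible extension, not implemented). Nodes below a 10⁻⁶ weight floor are
skipped at prediction. With τ² = 0 the predictor interpolates the data
exactly; far from all data it reverts to μ₀ with sd √σ².

## The geostatistical model

Cluster rates are modelled as y = β₀ + Σβⱼxⱼ + Σfₖ(xₖ) + u(s) + ε with
mean-zero Gaussian priors (sd 10 on standardized covariates) on all
coefficients, penalized cubic B-spline smooths (quantile knots,
second-difference penalty, iid ridge on the penalty null space), a Matérn
field u over the cluster sites, and iid nugget ε. Smooths are available
but off by default: determinants analyses of this kind report single
coefficients per covariate, which implies linear terms.

Because the likelihood is Gaussian, the posterior of all coefficients and
site-level field values given the hyperparameters is exactly Gaussian and
is computed by one Cholesky factorization per hyper node; the marginal
likelihood comes from the matrix-determinant identity on the same
factorization, avoiding any dense n × n inversion beyond the site
correlation matrix (cached per range value). Hyperparameters (σ², φ, τ²,
smooth penalties) take a flat prior on a data-driven grid: the nugget grid
spans 0.2–1.1 × the OLS residual variance, σ² spans 0.05–1 × it, and φ
spans 8–50% of the cluster bounding-box diagonal (3 × 3 × 4 nodes by
default). Posterior summaries are Gaussian-mixture moments over the node
weights, with 95% credible bounds found by bisecting the mixture CDF to
10⁻⁶. Model comparison uses the mixed log marginal likelihood
(log-mean-exp of node evidences under the flat grid prior); ties are
reported when the difference falls inside a caller-chosen band.

This exact-GP formulation over cluster sites replaces the SPDE
triangular-mesh machinery: the target model is the same, and at n ≲ 3,000
sites dense conditioning is both feasible and free of mesh-approximation
error. It is the package's single structural deviation from the usual
computational route for such models.

## Prediction and aggregation

At each pixel the fixed-effect contribution (training-standardized
covariates) is added to the Gaussian-process conditional of u given its
site-level posterior, per hyper node; node results are mixed as above.
Rate surfaces are floored at 0 after mixing, since the Gaussian model
admits negative excursions. Admin-level estimates are population-weighted
means of the pixels whose centres fall in each unit (pixel membership by
centre; border pixels belong to exactly one unit); a zero-population unit
falls back to the unweighted mean and is flagged, and area weighting is
available behind a flag. Credible bounds are aggregated with the same
weights — an approximation, since exact interval aggregation requires the
joint posterior across pixels (e.g. by joint simulation); the
approximation is conservative in practice and is documented wherever the
tables are written.

## Synthetic-data generator

The generator is the package's study-conditions fixture: a flat projected
region (default 100 × 100 km at 1 km), five covariate surfaces (Euclidean
distance to 3 seeded cities and 25 health facilities — a pixel containing
a seeded point is at distance 0 by convention; altitude and log-normal
population density as Gaussian-smoothed noise with a 10 km correlation
length; a logistic-smooth religious-proportion surface), a Matérn field
drawn exactly on a ≤ 50 × 50 coarse lattice and bilinearly refined, and
stratified clusters (uniform locations; the round(urban_fraction · n)
clusters nearest a city are urban; two-stratum design weights 0.8/1.25
normalized to mean 1 — no nonresponse adjustment is modelled). The local
truth is TFR(s) = β₀ + Σβⱼ Xstd,ⱼ(s) + u(s), floored at 0.2 to keep the
Gaussian linear predictor from implying negative rates. Women are uniform
in age 15–49 at interview (the within-cluster age distribution of real
surveys is not specified anywhere authoritative; uniform is the neutral
choice); births per age-group segment of the 36-month window are Poisson
with rate exposure · schedule_a · TFR(s)/TFR_base and birth months uniform
in the segment — the standard piecewise-constant-hazard approximation,
which makes the direct estimator unbiased by construction. The default
schedule (0.10, 0.23, 0.22, 0.16, 0.11, 0.06, 0.02 births per woman-year)
sums to 0.9, i.e. a baseline TFR of 4.5 — a high-fertility sub-Saharan
profile; default effects (0.42, 0.17, 0.37, 0.14, −0.01) echo the
magnitudes of published determinants analyses; the default field has
σ² = 0.25 and φ = 30 km. Cluster-level religious proportions are binomial
draws from the true surface with the cluster's women as denominator.

What the generator does *not* emulate: GPS displacement of cluster
coordinates (buffer averaging in the covariate module is the countermeasure
on real data), non-uniform age structure, parity-dependent birth spacing,
multi-survey temporal dependence (years are independent replicates), and
irregular admin boundaries (units are nested rectangles snapped to pixel
edges). Passing tests therefore demonstrate correctness of the estimators
and inference under the assumed model, not robustness to these real-data
features.

All randomness flows from one integer seed through named substreams
(SHA-256 of "seed:stage", reduced below 2³¹), so stages are individually
reproducible and inserting a stage does not perturb the others; identical
seed and configuration give byte-identical outputs, checksummed in the
pipeline manifest.

## Numerical choices

Cholesky factorizations carry an escalating diagonal jitter starting at
10⁻¹⁰ × the mean diagonal (10⁻⁸ in the kriging likelihood); failure after
8 escalations raises an error naming the jitter reached. Fit nodes require
a strictly positive nugget (the evidence identity divides by it); the
kriging grid may include τ² = 0, where interpolation is exact to the
jitter. Mixture quantiles bisect to 10⁻⁶. Degenerate inputs — zero-area
extents, zero-variance covariates, partitions finer than the grid,
negative weights, children born after interview — raise errors naming the
offending object.

## Problem sizes

The shipped validation uses the sizes a desk machine handles comfortably:
parameter recovery averages 20 surveys of 500 clusters × 25 women;
interval coverage uses 50 replicates of 250 clusters drawn from the
Gaussian observation model directly (the calibration question is about the
inference, not the birth-history layer); model selection uses 20 + 20
replicates of 200 clusters; the end-to-end pipeline default is 250
clusters on a 100 × 100 grid. These choices are stated here because the
resulting Monte-Carlo resolution (e.g. ±0.03 on recovery bias) is part of
what the reported numbers mean.

## Known limitations

Gaussian likelihood on cluster-level rates ignores the heteroscedastic
sampling noise of the direct estimator (clusters with fewer woman-years
are noisier); the nugget absorbs it on average. Credible-interval
aggregation is approximate (above). ν is fixed rather than estimated.
Kriging of proportions is on the identity scale. Per-year models are
independent; no temporal smoothing is attempted.
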