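# Methods

`podomap` implements a two-stage mapping workflow for podoconiosis (and,
with different covariates, any low-prevalence environmentally driven
condition surveyed at community level), plus the burden arithmetic that
turns prevalence surfaces into case counts, and a synthetic-world
generator that makes the whole chain testable against a known truth.

## Stage 1 — environmental suitability ensemble

Communities are labelled endemic (1) if they recorded at least one
confirmed case and non-endemic (0) otherwise.  Because survey effort is
geographically biased (one region screened near-exhaustively, the rest
sparsely sampled), training on the raw labels would let the learners
model *where surveys happened* rather than *where the environment permits
the disease*.  Three corrections are applied:

1. **Positive thinning.**  A random 75% subset of the positive
   communities inside the over-represented region is retained.
2. **Bias-matched background points.**  Occurrence records are counted
   per 1-km cell, smoothed with an isotropic Gaussian kernel (bandwidth:
   Silverman's rule on the occurrence coordinates, configurable), and
   renormalised into a sampling-bias density.  500 background
   (pseudo-absence) points are drawn from this density, with replacement,
   at cell centres — so the background carries the same geographic bias
   as the presences.
3. **Weight balancing.**  Presences carry weight 1; observed absences
   and background points share the common weight
   n_presence / (n_absence + n_background), so the two sides of the
   classification problem have equal total mass.

Two learners are fitted per replicate: gradient-boosted regression trees
(learning rate 0.005, interaction depth 4 — allowing up to four-way
interactions — tree count by early stopping on a 10% internal validation
fold, capped at 5000) and a random forest (500 trees, √p features per
split).  Each of the `n_reps` (default 100) replicates draws a stratified
80/20 split of the *surveyed* records; background points join every
training fold but are never evaluated against, since they are
constructed data, not observations.  Held-out performance is measured by
AUC (rank/Mann–Whitney with tie correction), TSS (sensitivity +
specificity − 1 at the Youden-optimal threshold) and PCC.  Replicates
with AUC < 0.8 or TSS < 0.7 are discarded; the ensemble surface is the
per-cell mean of the survivors with empirical 2.5/97.5-percentile bands
(reported ensemble "confidence intervals" in this literature rarely come
with a formula; the empirical percentile band is this package's explicit
choice, and the distribution of per-replicate optimal thresholds is
reported alongside).

The continuous suitability surface becomes a binary environmental-limits
map at the cut-off maximising (sensitivity + specificity + PCC)/3 over
all score midpoints, ties resolved toward the lower threshold.  Partial
dependence (definition-level: average prediction with one covariate
pinned) and normalised variable contributions are emitted per learner.

## Stage 2 — binomial geostatistical model

For community i with n_i screened and y_i cases at location x_i:

    y_i | p_i ~ Binomial(n_i, p_i)
    logit p_i = d(x_i)'β + S(x_i) + Z_i

with S a zero-mean stationary Gaussian process, exponential covariance
σ² exp(−u/φ) (Matérn κ = 0.5; κ is configurable but the exponential is
the default family), and Z_i ~ N(0, τ²) iid the nugget — unstructured
between-community variation below the modelled spatial scale.

**Inference** is Monte-Carlo maximum likelihood with a Laplace
importance-sampling proposal:

1. Initial values: β from a non-spatial binomial GLM; (σ², φ, τ²) from a
   weighted-least-squares exponential fit (Cressie weights) to the
   empirical semivariogram of the GLM's empirical-logit residuals.
2. Laplace stage: Nelder-Mead over (log σ², log φ, log τ²) of the profile
   Laplace likelihood, the latent mode found by damped Newton over
   (β, U) jointly; three random restarts guard against local optima.
3. MCML polish: 400–500 antithetic draws from the Gaussian (Laplace)
   approximation of p(U | y) at the stage-2 optimum serve as importance
   proposal; the Monte-Carlo likelihood ratio is maximised over all
   parameters with common random numbers.

Standard errors come from the observed information (central-difference
Hessian) of the Laplace log-likelihood in (β, log σ², log φ, log τ²).

**Prediction** targets prevalence = logit⁻¹(d'β + S) at unsampled cells —
the nugget is excluded, being community-level noise rather than part of
the spatial surface.  Joint predictive samples combine (a) β drawn from
its asymptotic normal (diagonal covariance; coefficient
cross-correlations are conservatively dropped), (b) the observed latent
field from its Laplace Gaussian posterior, and (c) S at prediction cells
from the conditional GP given that field.  Cells outside the
environmental-limits map get prevalence 0 and a flag.  Reported
surfaces: predictive mean, 2.5/97.5 percentiles, per-cell SE (sample
standard deviation; multiplied by adults downstream it is the SE of
predicted case counts), and the exceedance probability
P(prevalence > threshold), default threshold 1% — the conventional
endemicity cut-off for intervention planning.

**Validation** compares the empirical semivariogram of standardised
empirical-logit residuals with a *global* 95% Monte-Carlo envelope under
the fitted model: the pointwise quantile level is widened until 95% of
simulated variogram curves lie entirely inside, making "all bins inside"
a calibrated whole-curve test.  A pointwise 2.5/97.5 band would reject a
correctly specified model in roughly 40% of datasets once split over a
dozen bins, which is why the simultaneous construction is used.  The
check passes when ≥ 95% of bins fall inside.

## Burden arithmetic

Adults per cell = population × adult fraction (scalar or raster).
Cases per cell = predicted prevalence × adults, with the 95% CI surfaces
propagated through the same product.  Population at risk = adults in
cells where the binary limits map is 1.  Zonal aggregation assigns each
cell to the polygon containing its centre (boundary-inclusive,
first-claim tie rule in list order); cells in no polygon accumulate in an
`unassigned` row so unit sums always equal grid totals exactly.  Case
counts stay real-valued until presentation: published tables round, which
is why the summariser computes shares from column sums rather than from
printed grand totals.

## Synthetic worlds

The generator emulates the structure of a national podoconiosis dataset:

- **Covariates**: stationary Gaussian fields with per-covariate
  correlation ranges (default 5–20 km on a 60×60 km grid), standardised.
  Simulation is exact (Cholesky of the cell-to-cell exponential
  correlation), which caps worlds at 10 000 cells; exactness is what
  makes parameter-recovery tests meaningful.
- **Truth**: p(x) = logit⁻¹(d(x)'β + S(x)); binary suitability
  = p(x) > floor.
- **Surveys**: 748 communities at distinct cell centres, 90% inside one
  oversampled rectangle (the near-exhaustively screened region); n
  screened ~ Uniform(100, 500) (mean ≈ 300, matching the screening effort
  of the emulated surveys); cases ~ Binomial(n, logit⁻¹(logit p + z))
  with z ~ N(0, τ²) the community nugget on the logit scale — the same
  scale the geostatistical model assumes, so recovery tests are
  well-posed.
- **Population / admin**: a log-Gaussian density surface scaled to a
  total, and a rectangular partition written as GeoJSON.

Default coefficients β = (−9, 3.5, −2, 1.2, 0, 0) with suitability floor
0.0025 were calibrated once so the simulated surveys reproduce the
emulated regime: ≈ 60% zero-case clusters on average, ≈ 40% endemic
communities, and ensemble member AUC/TSS in the 0.8–0.95 band.  The
floor sits at ln 2 / n̄ — the prevalence at which a community of average
screening effort has a 50% chance of recording a case — aligning the
label boundary with the truth boundary; without that alignment,
"suitable" and "detectable" diverge and no learner can score well against
the truth, however good it is.  The `strong_signal_config` preset
(σ² = 0, slopes 5/−3/2, heavier screening) describes an ecology fully
determined by covariates and is the regime used to measure ensemble
recovery.

What the generator does **not** emulate: sensor artefacts and cloud
masks, dasymetric population models, non-stationary covariate effects,
household-level risk factors, and preferential sampling (survey
locations are independent of the latent field).  Passing tests therefore
demonstrate correctness of the estimators under the assumed model
family, not robustness to the full messiness of real remote-sensing
data.

## Numerical choices

- Cell containment is half-open ([x₀, x₀+Δ) × (y₀−Δ, y₀]): points on
  shared edges belong to the cell right/below, making extraction
  deterministic.  Nearest-neighbour resampling inherits the same tie
  rule on half-cell boundaries.
- Slope uses Horn's 3×3 operator (the conventional GIS choice) with
  replicated borders, i.e. one-sided differences at edges.
- Distance and slope refuse geographic (degree) CRS identifiers rather
  than silently treating degrees as km.
- Covariances get a 1e-10 jitter before factorisation; covariance
  parameters are optimised on the log scale within generous bounds
  (log σ², log τ² ∈ [−12, 8]); σ̂² ≈ 0 triggers a "no spatial signal"
  warning rather than an error.
- All stochastic steps derive from one master seed:
  `SeedSequence([seed, crc32(stage)])` per pipeline stage,
  `SeedSequence([seed, rep, algo])` per ensemble replicate.

## Problem sizes in the test-suite and acceptance script

Simulation studies run at sizes chosen to make their statistical targets
meaningful but no larger: parameter recovery at 300 communities on a
40×40 km world (10–20 replicates), ensemble recovery at ~2000 labelled
cells, variogram self-consistency at 120 communities with 150–200
Monte-Carlo simulations.  These sizes are the package's reference study
conditions; the pipeline itself scales to any world within the exact-GP
ceiling.

## Known limitations

- The Laplace/MCML engine uses dense covariance algebra: fits are
  comfortable to ~1000 communities and prediction to a few thousand
  cells; country-scale 1-km grids need the low-rank approximations this
  package deliberately leaves out of scope.
- β predictive uncertainty ignores coefficient cross-correlations
  (diagonal approximation) and the uncertainty of (σ², φ, τ²) is not
  propagated into prediction — intervals are mildly anti-conservative,
  the standard plug-in compromise.
- φ and σ² are only weakly identified from 300 clustered communities
  (recovery within a factor of two in ~80–90% of replicates); τ² is much
  better identified, consistent with short-range variation dominating
  cluster surveys.
- GeoTIFF I/O is intentionally absent: rasters are exchanged as ESRI
  ASCII grids (plain text) plus a layer manifest, and polygons as
  GeoJSON.
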