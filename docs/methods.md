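# Methods

## Model

`icebears` estimates the abundance of polar bear groups on sea ice from two
aerial survey platforms flown over a common grid (cells of roughly
25 × 25 km) during a multi-week spring window. The population is assumed
closed over the survey — a fixed number `N` of groups neither enters nor
leaves the study area — but groups redistribute freely each day as
conditions (chiefly ice) change. Occupancy probabilities follow a
multinomial link,

    pi_st = A_s exp(nu_st) / sum_s A_s exp(nu_st),

with `A_s` the saltwater-habitat area of cell `s` (cell area × saltwater
proportion) and `nu` an intercept-free linear predictor. The closure +
redistribution assumption is what stabilizes estimation when total counts
are in the dozens; its cost is that `N` must be read as "average number of
groups present while surveying", not a snapshot census.

### Occupancy predictor

`nu_st` contains:

* penalized cubic regression spline smooths (maximum basis dimension 6) of
  ice concentration, RSF (telemetry-derived relative habitat use), easting,
  northing, and distance to land. Distance to land, easting and northing
  are standardized by division by their grand means (each then averages
  1.0); ice and RSF stay on their natural scales.
* a fixed coefficient of −50 on the `water99` indicator (ice concentration
  below 1%). This is a hard gate, not an estimated effect: it forces
  occupancy in open water to zero (`exp(−50) ≈ 2e−22`) while keeping the
  likelihood smooth.
* a linear fixed effect of latent track intensity `Z_st`, entered on its
  natural (intensity) scale after division by its grand mean. The
  literature this model descends from does not pin down the transformation;
  the natural scale was chosen because the track surface is itself already
  an exponential of the habitat covariates, and the standardization keeps
  the coefficient's scale comparable to the smooth terms. The estimated
  track effect is weakly identified either way.

### Track submodel

Track observations are joined across platforms through a "blocky" Poisson
point process with intensity `Z_st` (track features per km², constant within
a cell-day): a photograph of ground footprint `B = 0.012 km²` contains at
least one track with probability `1 − exp(−B Z)`, and a visual observer
flying `L` km through a cell reports `Poisson(L η Z)` tracks. The scaling
`η` absorbs the unknown effective strip width for tracks and the observers'
rules for delineating distinct tracks; it is entirely confounded with the
track intercept when only visual data exist (a rank deficiency the test
suite demonstrates), which is precisely why the two platforms are fitted
jointly. `log Z = x'β` with a fixed polynomial design (intercept, distance
to land and its square, ice and its square, RSF) plus the same −50 ·
water99 offset as the occupancy predictor. Tracks are modeled as spatially
independent, which they are not (tracks are continuous features); the model
accepts this misspecification because `Z` serves as a predictive index, and
surfaces lack of fit through the residual diagnostics instead.

### Detection

Counts are Poisson-thinned with compound detection `p_st = θ_st a_st`:

* Thermal platform: `θ = p_us`, informed by experimental flyover trials
  `D ~ Binomial(n, p_us)` jointly with the counts; coverage `a` is
  photographed footprint over `A_s`.
* Visual platform: `θ = p_rus = g(0) (1/w) ∫_0^w exp(−x²/2σ²) dx`, the
  average of a half-normal detection function over a strip truncated at
  `w = 600 m` (fixed strip width 1.2 km, 0.6 km per side); coverage is
  `L · 1.2 / A_s`, clipped to 1. The trackline probability `g(0)` cannot be
  estimated from single-platform data and is a fixed scenario input,
  reported at 0.6, 0.8 and 1.0; abundance is strictly decreasing in it.
* The perpendicular-distance likelihood conditions on detection (standard
  line-transect form), so `g(0)` enters only through `p_rus`. A
  uniform–half-normal mixture detection function is available for
  comparison, flat to the photo-reach breakpoint (350 m) and declining
  half-normally beyond it; the join is continuous
  (`exp(−(x²−b²)/2σ²)` for `x > b`), the weakest assumption consistent
  with a uniform segment, and the form reduces to the pure half-normal as
  `b → 0`.
* Auxiliary visual counts from the thermal platform (sightings without
  distances, often beyond the thermal swath) are `Poisson(ξ N π p)` with a
  single estimated relative-detectability ratio `ξ`, assumed constant over
  the survey.

### Group size and total abundance

Counts are of groups; observed group sizes are shifted-Poisson,
`(g−1) ~ Poisson(μ_g − 1)`, pooled across platforms (their reported means
differ only descriptively). The MLE of `μ_g` is the sample mean. Total bear
abundance is `N* = μ_g N`, with a delta-method SE from the joint Hessian
and a 95% log-based interval `N* exp(±1.96 √log(1+CV²))`, multiplicatively
symmetric (`lower · upper = N*²`).

### Marginal likelihood and inference

The joint negative log likelihood sums the track, thermal-count,
auxiliary-count, visual-count, flyover, distance, and group-size terms plus
the spline priors. Spline coefficients `α` are random effects with
block-diagonal precision `λ_i S_i` (`S_i` the integrated-squared-second-
derivative penalty); they are integrated out with a Laplace approximation
at their conditional mode. Smoothing parameters carry Gamma(0.05, 0.005)
priors (mean 10) and are *optimized* on the log scale together with the
other fixed parameters — an empirical-Bayes treatment of the formal
integral over `λ`, matching standard practice in the random-effects
software this class of model is usually fitted with; the Jacobian of the
log-scale parameterization is included. Only `α` is Laplace-integrated.

## Synthetic data

The generator is the package's substitute for the (non-public) survey data
and defines its reference study conditions: a 20 × 20 lattice of 25-km
cells, 10 survey days, 600 groups of mean size 1.4, σ = 250 m, η = 0.05,
ξ = 1.5, p_us = 0.67, 12 flyover trials. Effort defaults — 60 visual cells
per day at 25 km each, 30 thermal cells per day at 10 km² photographed —
were chosen so that the expected number of detected groups (≈ 40, split
roughly 26 visual / 4 thermal / 7 auxiliary) mirrors the scale of the
survey this model class was developed for (52 groups). Every stream is
drawn from exactly the model's distributions, in order: latent `Z`;
binomial photo-track indicators; Poisson observer tracks; a fresh
`Multinomial(N, π_t)` placement each day (no movement kernel — matching
the closure-with-redistribution assumption); Poisson counts with compound
thinning; inverse-CDF truncated half-normal distances; shifted-Poisson
group sizes; binomial trials. A scenario (including its seed) fully
determines the output.

Geography is stylized: land is an L-shaped edge (the full southern boundary
plus the southern 40% of the western boundary), so distance-to-land
correlates strongly (≈ 0.85) but not perfectly with northing, as for a real
coastline — with a single straight coast the two covariates coincide and
the smooth set loses a dimension outright. Ice starts near-complete and
melts southward with spatially smooth structure, pushing late-season
coastal cells under the 1% open-water threshold; unreliable coastal ice is
emulated by deleting a fraction of coastal values and refilling them by
inverse-distance weighting (power 2, 8 neighbors), a documented stand-in
for geostatistical kriging. The RSF is a positive smooth random field with
mean 1.

What passing tests on these data do **not** show: robustness to
overdispersed counts, track spatial autocorrelation, animal movement
autocorrelation across days, preferential effort allocation, sea-ice drift,
or real projections/coastlines — none of which the generator produces.
They show that the estimator is consistent and approximately calibrated
when its own assumptions hold (which is also all that a correctly specified
hierarchical model can promise).

## Numerical choices

* **Inner problem.** The conditional mode of `α` (dimension 25: five
  smooths × five coefficients after the sum-to-zero constraint is absorbed
  by QR) is found by damped Newton with analytic gradient and Hessian of
  the Poisson-softmax objective; the exact Hessian is used when positive
  definite, otherwise a ridged Gauss–Newton surrogate. Convergence target
  is gradient ∞-norm ≤ 1e−8; once the Newton decrement is small the solver
  switches to full undamped steps, because the Laplace log-determinant is
  first-order sensitive to residual mode error and the marginal objective
  must be smooth to ~1e−8 for finite-difference outer derivatives.
* **Propriety ridge.** A weak ridge (1e−4, i.e. a N(0, 100²) prior on each
  coefficient) is added to the spline precision. The penalty null spaces
  (linear trends) are otherwise improper, and with correlated covariates
  the data can leave a combination of them almost flat, making the Laplace
  determinant undefined. The ridge is configurable (`null_ridge`),
  negligible relative to data information (smallest data eigenvalues are
  ~1e3 larger), and the prior normalizing constant uses the exact
  full-rank determinant when it is active.
* **Outer problem.** 17–18 fixed parameters, all on unbounded (log/logit)
  scales with wide box bounds as safety rails. Gradients are finite
  differences, so the objective is first preconditioned by the square root
  of its diagonal curvature — track-likelihood directions are up to four
  orders of magnitude stiffer than abundance directions, which defeats
  quasi-Newton methods on the raw scale. An L-BFGS-B warmup is followed by
  damped Newton with a central-difference Hessian (eigenvalue-floored, so
  saddle-safe), to a preconditioned gradient tolerance of 1e−3; the final
  Hessian doubles as the SE/covariance source. A singular Hessian is
  reported and suppresses intervals rather than failing the fit.
* **Initialization** is data-driven: track parameters from a track-only
  fit, σ from a distance-only fit, `p_us` from the trial proportion, `μ_g`
  from the group-size mean, `ξ` from the auxiliary/thermal count ratio,
  `N` from a moment estimate assuming uniform occupancy over iced cells,
  λ at its prior mean 10.
* **Spline bases** are cubic B-splines with boundary knots at the data
  range and interior knots at quantiles; penalties are computed exactly by
  two-point Gauss–Legendre per knot span (the second derivative is
  piecewise linear). Quantile ties are nudged apart; a constant covariate
  raises an error advising removal. Dropping a collinear smooth (e.g.
  distance-to-land when it nearly duplicates northing) is done by passing
  a reduced covariate list to `build_smooths`; the default retains all
  five.
* **Degenerate inputs.** Parameters with no informative stream are frozen
  automatically (ξ without auxiliary counts, σ without distances, track
  parameters without track data); `μ_g` is pinned to 1 when no group
  exceeds one. Counts with zero recorded effort are rejected at validation.
  Cells with no saltwater habitat get occupancy exactly 0.
* **Diagnostics.** Randomized quantile residuals use the lower-CDF
  convention `P(Y < y) + u P(Y = y)`, which is Uniform(0,1) under the
  model (the often-printed `F(y) + u f(y)` exceeds 1 with positive
  probability). Randomization deviates are seeded and recorded. Uniformity
  is tested by χ² with 10 equal bins, one panel per submodel.

## Problem sizes

The test suite and acceptance script run the full pipeline at the reference
conditions (400 cells × 10 days, ~40 detected groups per replicate; 50
replicates for the calibration study), chosen to match the generator's
study conditions; a single fit takes a few seconds on one core.

## Known limitations

* `g(0)` is an assumption, not an estimate; results are reported per
  scenario and only their envelope is defensible.
* Empirical-Bayes `λ` ignores smoothing-parameter uncertainty in the SEs;
  with five smooths and weak data the priors do real work.
* Poisson count and track likelihoods carry no overdispersion; lack of fit
  appears in the residual panels instead of the intervals.
* Regional interval endpoints rescale the total-abundance CV rather than
  propagating region-specific uncertainty.
* The closed-population assumption biases interpretation toward "average
  abundance during the survey window" when movement across the boundary is
  non-negligible.
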