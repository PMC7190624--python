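# Methods

This note records the models implemented in `snowtrack`, the choices
made where the design was genuinely open, and what the synthetic world
does and does not establish.

## The synthetic world

**Snowmelt front.**  Snow is binary (the analysed satellite product is
binary after cloud/darkness interpolation, so the simulator emits the
analysed variable, not a fraction).  A cell at latitude `y` on day `t`
is snow-covered when `logistic(k·(y − L(t))) > 0.5`, i.e. exactly when
it lies north of the front latitude `L(t) = L₀ + v·t`.  At any fixed
latitude the melt probability traces the classic sigmoid in time — slow
far from the front, fastest as the front passes.  Defaults: a 20°×20°
window (20–40°E, 55–75°N) at 0.25° cells over 1 Mar–30 Jun, `L₀ = 58°N`,
`v = 0.15°/day` (~17 km/day, a realistic spring snow-line pace), logistic
steepness `k = 1.5 /°`.  With the per-cell flip noise at 0 the melt is
deterministic and monotone (no re-freeze), which makes monotonicity
testable; a small flip probability (the demo uses 0.02) re-introduces
the patchy flicker of real binary snow maps and guarantees within-
stratum snow variation everywhere.

**Environmental fields.**  Temperature and NDVI are affine in
day-of-year (increasing) and latitude (decreasing) plus seeded Gaussian
noise — 0.25 °C/day and −0.8 °C/° for temperature, 0.006/day and
−0.012/° for NDVI (clipped to [−1, 1]): ballpark spring-warming and
green-up gradients, not a climate model.  Wind U/V are a configurable
mean vector (default u = 3, v = 1 m/s) plus a Gaussian-filtered random
field rescaled to a 3 m/s standard deviation.

**Agents.**  Each agent takes daily decisions: K candidate endpoints
(distance ~ Exponential(mean 50 km), heading ~ wrapped normal, SD 40°,
around the bearing toward its attraction latitude `L(t) + δ`), one of
which is chosen with probability ∝ `exp(β·x)` over the candidate
covariates.  The coupling offset `δ` (+2° AHEAD, 0 ON_FRONT, −2°
BEHIND) reproduces the high / intermediate / low snow-occupancy
phenotypes of irruptive, mixed and regular migrants; the spatial scale
over which occupancy percentages are quoted in the field is not fixed
anywhere, so `occupied_snow_fraction` exposes a neighbourhood-radius
parameter instead of hard-coding one (ordering, not percentages, is the
tested claim).  Every decision's full candidate set and covariates are
recorded, so the true β is recoverable exactly from the generator's own
strata.

**What a green test does not establish.**  The generator has no
orography, sea mask, cloud gaps, Argos positional error, or behavioural
states; its movement kernel (attraction-point bias) is not the kernel
the stratum builder assumes (previous heading + empirical turns).  A
consequence worth knowing: coefficients fitted to *re-built* strata are
attenuated relative to the generator's β, and directional persistence
can leak into wind covariates, because selection is always measured
relative to the builder's availability model.  Estimator correctness is
therefore validated on the generator's own candidate sets (or on
directly simulated strata), while re-built strata validate the pipeline
plumbing and qualitative signs.

## Track processing

* Argos classes are ordered 3 > 2 > 1 > 0 > A > B > Z; fixes below the
  configurable minimum (default 2, error > 500 m) are removed, GPS
  fixes never.  Tracks reduced below 3 fixes are dropped with a warning.
* Resampling is a greedy forward scan with a tolerance (default 10% of
  the step length): fixes closer than `step − tol` to the last kept fix
  are removed; the first fix inside `[step − tol, step + tol]` extends
  the burst; anything later closes the burst and anchors a new one.
  The rule is idempotent.  Bursts keep ≥ 2 fixes (singletons carry no
  step); turn angles exist from the second step of a burst.
* Distances are haversine on a 6371.0-km sphere, headings initial
  bearings; the sub-percent ellipsoidal error is irrelevant at raster
  resolution.  A zero-length step carries the previous heading and is
  flagged.  Year labels come from the first fix (spring migrations do
  not cross New Year).

## Segmentation

Forward first passage time: for each fix, the time until the linearly
interpolated trajectory first moves more than `r` (default 100 km) from
it, searching forward only — the simpler convention, stated openly.
Fixes whose remaining trajectory never exits are flagged undefined.
The migration segment is the longest run of sub-threshold fixes inside
the spring window (March–June by default); when no threshold is given
it is placed at the valley between the two modes of the log-FPT kernel
density (fast directed movement vs residence), falling back to the
median for unimodal profiles.  Radius, threshold and window are all
overridable; fixture-based tests pin the behaviour.

## Environmental annotation

Nearest-cell lookup on the point's own calendar date, no interpolation
(snow is binary; continuous variables use the same rule for
consistency); equidistant ties break toward the lower grid index, and a
point counts as on-grid within half a cell of the outer cell centres.
Day length uses the CBM declination/hour-angle formula with daylight
defined by the sun's centre at the horizon (polar day 24 h, polar night
0 h).  Wind support is `u·sin h + v·cos h`, crosswind `u·cos h − v·sin h`
(signed), which preserves `support² + crosswind² = u² + v²`.  The lag
table holds the location fixed and shifts the date by −10…+10 days; day
length is *recomputed at the shifted date* (the only reading under
which a day-length lag slope is meaningful — the fixed-date alternative
would be constant by construction); out-of-range shifted dates are kept
but flagged missing.  Daily wind/temperature fields coarsen the
6-hourly products used with real data; the analyses operate at ≥ 1-day
steps, so nothing downstream resolves sub-daily structure.

## Step-selection strata

The distance kernel is Exponential with MLE rate `1/mean(step length)`;
turn angles are resampled empirically with replacement (no parametric
claim is warranted for angles).  Kernels are fitted per dataset (a
species' pooled tracks); a per-individual option exists.  Alternatives
share the chosen step's start fix and get absolute bearings
`previous heading + turn draw`.  Snow is annotated at the endpoint on
the arrival date; wind is the decision-date field sampled at the start
fix and decomposed along each endpoint's *own* bearing (the
chosen-bearing alternative reading would make wind stratum-constant and
drop out of the conditional likelihood).  Wind covariates enter at the
one-day scale only.  Off-grid alternatives are redrawn up to 100 times
(clipping would distort the kernel near edges), then the stratum is
dropped and counted.

## Models

**Conditional logit.**  The exact stratum-softmax likelihood is
maximised by Newton's method with analytic gradient and Hessian
(observed information), starting at β = 0, gradient tolerance 1e−8.
Predictors without within-stratum variation are dropped (conditioning
removes stratum constants).  Divergence past |β| = 15 raises a
separation error naming the predictor.  The field-standard mixed
model here has a stratum-in-individual random effect; implementing
stratum-level random effects from scratch is out of proportion to what
the inferences use (signs and ΔAIC), so the package fits the exact
fixed-effects conditional likelihood and offers individual-level
cluster-robust (sandwich) SEs as the stand-in — a deliberate, stated
approximation.

**Lag models.**  Gaussian responses: ML linear mixed model with random
intercepts for individual and year-within-individual; when every
individual contributes a single year the year component is aliased with
the individual intercept and is dropped automatically.  Binary snow:
random-intercept binomial GLMM fit by maximising the per-group
Laplace-approximate marginal likelihood (`ℓ_g = h(b̂) − ½·log(σ²·(−h''(b̂)))`,
inner Newton for `b̂`), with the finest grouping (individual-year) as
the intercept level and no random slopes (only a grouping structure is
specified, not slopes).  SEs come from the numerical Hessian of the
marginal likelihood.  Fewer than two groups triggers a fixed-effects
fallback with a warning; constant responses return a flagged degenerate
fit.

**Comparison.**  `AIC = 2k − 2ℓ`; ΔAIC to the best candidate and Akaike
weights; candidates must share the data rows; "different" requires
ΔAIC strictly greater than 2.  The collinearity screen flags predictor
pairs with |Pearson r| ≥ 0.7 and zero-variance predictors.

## UHC validation

Strata are split by individual (default 30% of individuals held out;
strata within a bird are not independent).  Each of `n_resamples`
(default 1000) draws `β* ~ N(β̂, V̂)`, samples one "predicted used"
endpoint per test stratum with weights `exp(β*·x)`, and accumulates the
covariate distribution: Gaussian KDE (Silverman bandwidth frozen from
the observed used values) on a 100-point grid for continuous
covariates, the two-cell proportion vector for binary ones.  Coverage
is the fraction of grid points where the observed used distribution
lies inside the pointwise 2.5–97.5% envelope.  Covariates absent from
the model can still be evaluated — a missing selected covariate shows
up as lost coverage, which is the point of the check; a model-level
summary averages coverage across the evaluated covariates.  For a
binary covariate the two proportion cells are complementary, so
per-covariate coverage is all-or-nothing and carries the ~5% tail risk
of any 95% envelope; the averaged summary is the stable statistic.

## Numerical and degenerate-input conventions

Seeds are explicit everywhere; identical seed + config reproduces
rasters, tracks, strata and envelopes bit-for-bit.  Degenerate grids,
empty date ranges, negative tolerances, K < 2 and sub-3-fix tracks are
rejected or dropped with counted warnings; every record dropped by the
pipeline appears in its stage counts.

## Known limitations

No cloud-gap handling or reprojection (regular lon/lat only); no
integrated-SSF movement-kernel estimation (gamma/von Mises kernels are
out of scope); the conditional logit omits stratum-level random effects
(see above); the binomial GLMM uses a single intercept level rather
than nested variance components; UHC reports coverage, not calibration
slopes.
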