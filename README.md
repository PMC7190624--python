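# snowtrack

Spring-migration analysis of Arctic-breeding raptors against the
northward-receding snowmelt front.

Arctic migrants such as the snowy owl, rough-legged buzzard and peregrine
falcon time their spring migration against a narrow window of favourable
breeding conditions, and snow cover is both a constraint on their prey
and a candidate cue for their timing.  `snowtrack` implements the two
complementary analyses used to study this system, plus a synthetic world
with known ground truth to validate them end to end:

1. **Snowmelt tracking (environmental-lag models).**  At every used
   one-day location, snow cover, temperature, NDVI and day length are
   extracted not only on the day of use but at lags of −10…+10 days
   (location fixed, date shifted).  If a bird rides the melt front, snow
   at its locations declines steeply across the lag window.  The lag
   slope is estimated with mixed models — for a response `y` at lag
   `τ`:

   `y ~ τ` with random intercepts for individual and year-within-individual,

   Gaussian (ML) for the continuous responses and a Laplace-approximate
   binomial GLMM for binary snow.  A model with the day term is compared
   to one without by ΔAIC (support claimed only when ΔAIC > 2) and
   Akaike weights `w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)`.

2. **Step selection (conditional logistic regression).**  Tracks are
   resampled to 1/3/5-day steps; each observed step is matched with
   K = 10 alternative steps drawn from the same start point (distance ~
   Exponential fitted to observed step lengths, bearing = previous
   heading + empirical turn-angle draw).  The chosen-vs-alternative
   decision is fit by maximising the exact conditional (stratum-softmax)
   log-likelihood

   `ℓ(β) = Σ_s [ β·x_chosen − log Σ_j exp(β·x_j) ]`

   with snow cover, wind support and crosswind as covariates (wind at
   the one-day scale only) and cluster-robust SEs by individual.  Fits
   are validated with used-habitat-calibration (UHC) resampling: the
   covariate distribution at actually chosen test locations must lie
   inside the envelope predicted by resampling `β* ~ N(β̂, V̂)`.

Supporting machinery: Movebank-style CSV ingestion with CLS Argos
class filtering (classes below 2 removed, GPS untouched), first-passage-
time segmentation of spring migration, daily raster annotation
(nearest cell, same calendar date), astronomical day length (CBM
formula), and wind support/crosswind decomposition.

The synthetic generator builds a logistic snowmelt front moving north at
constant speed, smooth temperature/NDVI/wind fields, and softmax agents
with known selection coefficients whose latitudinal attraction point
sits ahead of, on, or behind the front — the irruptive / mixed / regular
migrant phenotypes.

## Worked example

```bash
snowtrack run-demo --out demo_out --n-individuals 20 --seed 42 --uhc-resamples 300
```

prints (about 30 s; 20 agents per coupling mode, true β_snow = −1):

```
AHEAD: occupied-cell snow fraction 0.89
ON_FRONT: occupied-cell snow fraction 0.15
BEHIND: occupied-cell snow fraction 0.01
```

— the agents coupled ahead of the melt front sit almost entirely on
snow, those behind it almost entirely on bare ground.  The per-mode
analysis directories contain the coefficient tables.  For the ON_FRONT
mode, `analysis_ON_FRONT/lag_models.csv` holds the lag slopes
(`est` per day, ΔAIC against the slope-free model):

```
   response    est    se  delta_aic  different
       snow -0.536 0.008  11812.283       True
temperature  0.214 0.003   4979.042       True
       ndvi  0.005 0.000   3937.926       True
 day_length  0.094 0.001   3923.097       True
```

Snow at the used locations falls steeply across the lag window (the
birds surf the melt front) while temperature, greenness and day length
rise — the expected signature of snowmelt tracking.  The one-day
step-selection fit in `analysis_ON_FRONT/ssf_models.csv` recovers a
negative snow coefficient (−0.87 ± 0.10 here; the generator's true
coefficient applies to its own candidate sets, so estimates from
re-sampled availability are attenuated), and at the three- and five-day
scales the snow effect is not supported by ΔAIC, mirroring the
scale-dependence seen in real raptor data.

The same pipeline runs on real inputs: a Movebank-style CSV plus daily
NetCDF rasters (`snow.nc`, `temperature.nc`, `ndvi.nc`, `wind_u.nc`,
`wind_v.nc` on a shared regular lon/lat grid):

```bash
snowtrack run-all --tracks-path tracks.csv --rasters-dir rasters/ --output-dir out/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the three-mode synthetic scenario from scratch with the
given seed, runs the complete pipeline for every coupling mode (ingest,
lag models, step-selection fits at all three scales, UHC validation),
prints per-mode record counts, and writes the results JSON to `--out`.
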