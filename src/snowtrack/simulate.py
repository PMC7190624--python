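"""Synthetic snowmelt landscapes and ground-truth movement agents.

The real study system is a northward-receding spring snow line crossed by
migrating raptors.  Here the melt front is a latitude L(t) that moves
north linearly in time; snow at a cell is the logistic
``P(snow) = 1 / (1 + exp(-k (lat - L(t))))`` thresholded at 0.5 (i.e.
snow iff the cell lies north of the front), optionally corrupted by
per-cell Bernoulli flips.  Melt therefore follows the classic sigmoid in
time at any fixed latitude: slow far from the front, fastest as the
front passes, slow again at the end.

Agents take daily steps chosen by a stratum softmax in known
coefficients beta over the same covariates the analysis later fits
(snow, wind support, crosswind), so the whole pipeline can be validated
against a known ground truth.  A coupling mode places each agent's
latitudinal attraction point ahead of (+delta), on (0), or behind
(-delta) the front, reproducing the high / intermediate / low
snow-occupancy phenotypes of irruptive, mixed, and regular migrants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geo
from .enviro import DAY, EnvRasterSeries, _as_day
from .ssf import endpoint_covariates
from .tracks import Track, TrackSet

log = logging.getLogger(__name__)

COUPLING_MODES = ("AHEAD", "ON_FRONT", "BEHIND")


@dataclass
class SnowFrontConfig:
    """Grid, date range and melt-front dynamics of the synthetic world.

    Defaults describe a 20x20 degree Arctic window over a full spring
    (Mar 1 - Jun 30) with the front starting at 58N and moving north at
    0.15 deg/day -- roughly 17 km/day, the pace of a spring snow line.
    """

    lon_min: float = 20.0
    lon_max: float = 40.0
    lat_min: float = 55.0
    lat_max: float = 75.0
    cell_deg: float = 0.25
    date_start: str = "2016-03-01"
    date_end: str = "2016-06-30"
    front_start_lat: float = 58.0
    front_speed_deg_per_day: float = 0.15
    melt_steepness: float = 1.5     # 1/deg, logistic slope in latitude
    noise_prob: float = 0.0         # per-cell Bernoulli flip rate
    seed: int = 0

    def __post_init__(self):
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be > 0")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate grid extent")
        if _as_day(self.date_end) < _as_day(self.date_start):
            raise ValueError("empty date range")
        if self.front_speed_deg_per_day < 0:
            raise ValueError("front speed must be >= 0")
        if not (0.0 <= self.noise_prob < 0.5):
            raise ValueError("noise_prob must lie in [0, 0.5)")

    @property
    def dates(self):
        d0, d1 = _as_day(self.date_start), _as_day(self.date_end)
        return np.arange(d0, d1 + DAY, DAY)

    @property
    def lats(self):
        return np.arange(self.lat_min, self.lat_max + 1e-9, self.cell_deg)

    @property
    def lons(self):
        return np.arange(self.lon_min, self.lon_max + 1e-9, self.cell_deg)

    def front_latitude(self, dates):
        """Melt-front latitude L(t), moving north linearly in time."""
        t = ((_as_day(dates) - _as_day(self.date_start)) / DAY).astype(float)
        return self.front_start_lat + self.front_speed_deg_per_day * t


def make_snow_series(config: SnowFrontConfig) -> EnvRasterSeries:
    """Binary daily snow rasters from the receding logistic front.

    With ``noise_prob == 0`` the melt is deterministic: a cell is
    snow-covered exactly while it lies north of L(t), so each cell's
    date-ordered snow sequence is non-increasing (no re-freeze).  Noise
    flips cells independently and may re-introduce flicker.
    """
    lats = config.lats
    lons = config.lons
    if lats.size == 0 or lons.size == 0:
        raise ValueError("degenerate grid (0 cells)")
    dates = config.dates
    L = config.front_latitude(dates)
    # logistic(k (lat - L)) > 0.5  <=>  lat > L(t)
    p = 1.0 / (1.0 + np.exp(-config.melt_steepness * (lats[None, :] - L[:, None])))
    snow = (p > 0.5).astype(np.int8)[:, :, None] * np.ones(lons.size, dtype=np.int8)
    if config.noise_prob > 0:
        rng = np.random.default_rng(config.seed)
        flip = rng.random(snow.shape) < config.noise_prob
        snow = np.where(flip, 1 - snow, snow).astype(np.int8)
    return EnvRasterSeries.from_arrays("snow", dates, lats, lons, snow)


def make_env_fields(config: SnowFrontConfig,
                    temp_day_coef: float = 0.25, temp_lat_coef: float = -0.8,
                    temp_base: float = 2.0, temp_noise_sd: float = 1.5,
                    ndvi_day_coef: float = 0.006, ndvi_lat_coef: float = -0.012,
                    ndvi_base: float = 0.15, ndvi_noise_sd: float = 0.03,
                    wind_mean=(3.0, 1.0), wind_sd: float = 3.0,
                    wind_smooth_cells: float = 4.0) -> dict:
    """Temperature, NDVI and wind U/V series on the snow grid.

    Temperature and NDVI are affine in day-of-year (increasing) and
    latitude (decreasing) plus seeded Gaussian noise; NDVI is clipped to
    [-1, 1].  Wind components are a configurable mean vector plus a
    smooth (Gaussian-filtered) seeded random field.  The affine
    references are the config's start date and front start latitude.
    """
    dates = config.dates
    lats = config.lats
    lons = config.lons
    rng = np.random.default_rng(config.seed + 1)
    t = ((dates - dates[0]) / DAY).astype(float)[:, None, None]
    lat = lats[None, :, None]
    shape = (dates.size, lats.size, lons.size)

    temp = temp_base + temp_day_coef * t + temp_lat_coef * (lat - config.front_start_lat)
    temp = temp + np.zeros(shape)
    if temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, temp_noise_sd, size=shape)

    ndvi = ndvi_base + ndvi_day_coef * t + ndvi_lat_coef * (lat - config.front_start_lat)
    ndvi = ndvi + np.zeros(shape)
    if ndvi_noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, ndvi_noise_sd, size=shape)
    ndvi = np.clip(ndvi, -1.0, 1.0)

    def smooth_field(mean):
        f = np.full(shape, float(mean))
        if wind_sd > 0:
            noise = rng.normal(0.0, 1.0, size=shape)
            noise = ndimage.gaussian_filter(noise, sigma=(0, wind_smooth_cells, wind_smooth_cells))
            sd = noise.std()
            if sd > 0:
                f = f + wind_sd * noise / sd
        return f

    out = {
        "temperature": EnvRasterSeries.from_arrays("temperature", dates, lats, lons, temp),
        "ndvi": EnvRasterSeries.from_arrays("ndvi", dates, lats, lons, ndvi),
        "wind_u": EnvRasterSeries.from_arrays("wind_u", dates, lats, lons, smooth_field(wind_mean[0])),
        "wind_v": EnvRasterSeries.from_arrays("wind_v", dates, lats, lons, smooth_field(wind_mean[1])),
    }
    return out


@dataclass
class AgentConfig:
    """Ground-truth movement agents stepping over the synthetic world.

    ``beta`` are the true selection coefficients of the stratum softmax
    over (snow, wind_support, crosswind); ``coupling`` offsets each
    agent's latitudinal attraction point from the melt front by
    +offset_deg (AHEAD), 0 (ON_FRONT) or -offset_deg (BEHIND).
    """

    n_individuals: int = 20
    n_steps: int = 40
    step_interval_days: int = 1
    coupling: str = "ON_FRONT"
    beta: dict = field(default_factory=lambda: {"snow": -1.0, "wind_support": 0.05, "crosswind": 0.0})
    step_mean_km: float = 50.0
    K: int = 10
    seed: int = 0
    offset_deg: float = 2.0
    heading_sd_deg: float = 40.0  # wrapped-normal spread of candidate headings
    start_jitter_deg: float = 0.5

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_steps < 3:
            raise ValueError("steps per track must be >= 3")
        if self.coupling not in COUPLING_MODES:
            raise ValueError(f"coupling must be one of {COUPLING_MODES}")

    @property
    def lat_offset(self):
        return {"AHEAD": self.offset_deg, "ON_FRONT": 0.0, "BEHIND": -self.offset_deg}[self.coupling]


@dataclass
class SimulationResult:
    trackset: TrackSet
    strata: pd.DataFrame   # ground-truth strata, same long layout as ssf.build_strata
    beta: dict
    config: AgentConfig


def _bias_bearing(lat, target_lat):
    return 0.0 if target_lat >= lat else 180.0


def simulate_agents(agents: AgentConfig, rasters: dict,
                    front_config: SnowFrontConfig) -> SimulationResult:
    """Simulate agents whose step choice is a softmax in known beta.

    At each decision an agent draws K candidate endpoints (exponential
    distance, wrapped-normal heading around the bearing toward its
    attraction latitude ``L(t) + offset``) and picks one with probability
    proportional to ``exp(beta . covariates)``.  Every decision's full
    candidate set and covariates are recorded as ground-truth strata.
    Agents whose candidates cannot be kept on the grid are truncated
    there (kept if >= 3 fixes remain).
    """
    rng = np.random.default_rng(agents.seed)
    snow = rasters["snow"]
    beta_vec = agents.beta
    dates = snow.dates
    lon_lo, lon_hi = snow.lons[0], snow.lons[-1]

    tracks = []
    strata_rows = []
    stratum_id = 0
    for ind_i in range(agents.n_individuals):
        ind = f"{agents.coupling}_{ind_i:03d}"
        date = dates[0]
        target0 = front_config.front_latitude(date) + agents.lat_offset
        lon = float(rng.uniform(lon_lo + 0.2 * (lon_hi - lon_lo), lon_hi - 0.2 * (lon_hi - lon_lo)))
        lat = float(np.clip(target0 + rng.normal(0, agents.start_jitter_deg),
                            snow.lats[0] + 0.5, snow.lats[-1] - 0.5))
        fixes = [(date, lon, lat)]
        truncated = False
        for _ in range(agents.n_steps):
            date1 = date + agents.step_interval_days * DAY
            if date1 > dates[-1]:
                break
            target_lat = front_config.front_latitude(date) + agents.lat_offset
            bias = _bias_bearing(lat, target_lat)
            # draw candidates, redrawing off-grid ones a few times
            cand_lon = np.empty(agents.K)
            cand_lat = np.empty(agents.K)
            need = np.ones(agents.K, dtype=bool)
            for _try in range(50):
                n = int(need.sum())
                if n == 0:
                    break
                d = rng.exponential(agents.step_mean_km, size=n)
                brg = rng.normal(bias, agents.heading_sd_deg, size=n) % 360.0
                clon, clat = geo.destination(lon, lat, brg, d)
                cand_lon[need] = clon
                cand_lat[need] = clat
                need = ~snow.in_bounds(cand_lon, cand_lat)
            if need.any():
                truncated = True
                break
            cov = endpoint_covariates(lon, lat, date, date1, cand_lon, cand_lat,
                                      rasters, include_wind=True)
            eta = np.zeros(agents.K)
            for name, b in beta_vec.items():
                if name in cov:
                    eta = eta + b * cov[name].to_numpy()
            w = np.exp(eta - eta.max())
            w /= w.sum()
            choice = int(rng.choice(agents.K, p=w))
            case = np.zeros(agents.K, dtype=int)
            case[choice] = 1
            block = pd.DataFrame({
                "stratum": stratum_id, "individual": ind,
                "year": int(str(date)[:4]), "date": np.repeat(date, agents.K),
                "case": case, "lon": cand_lon, "lat": cand_lat,
                "start_lon": lon, "start_lat": lat,
            })
            strata_rows.append(pd.concat([block, cov], axis=1))
            stratum_id += 1
            lon, lat = float(cand_lon[choice]), float(cand_lat[choice])
            date = date1
            fixes.append((date, lon, lat))
        if truncated:
            warnings.warn(f"agent {ind} left the grid; track truncated at {len(fixes)} fixes",
                          stacklevel=2)
        if len(fixes) < 3:
            continue
        df = pd.DataFrame(fixes, columns=["timestamp", "lon", "lat"])
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        df["individual"] = ind
        df["sensor"] = "gps"
        df["argos_class"] = np.nan
        year = int(df["timestamp"].dt.year.iloc[0])
        tracks.append(Track(ind, year, df[["individual", "timestamp", "lon", "lat",
                                           "sensor", "argos_class"]]))
    strata = (pd.concat(strata_rows, ignore_index=True) if strata_rows
              else pd.DataFrame())
    return SimulationResult(TrackSet(tracks), strata, dict(beta_vec), agents)


def simulate_strata(n_strata: int, K: int = 10, beta: dict | None = None,
                    seed: int = 0, snow_prob: float = 0.4,
                    n_individuals: int = 10,
                    continuous_covariates: tuple = ()) -> pd.DataFrame:
    """Directly simulate SSF strata with known coefficients.

    A lightweight generator for estimator-calibration studies: each
    stratum holds K+1 endpoints whose snow covariate is Bernoulli(p) and
    whose optional continuous covariates are standard normal; the chosen
    endpoint is drawn by the softmax in ``beta``.  Strata are assigned
    round-robin to ``n_individuals`` for cluster-robust inference.
    """
    beta = {"snow": -1.5} if beta is None else beta
    rng = np.random.default_rng(seed)
    m = K + 1
    cols = {"snow": rng.binomial(1, snow_prob, size=(n_strata, m)).astype(float)}
    for name in continuous_covariates:
        cols[name] = rng.normal(size=(n_strata, m))
    eta = np.zeros((n_strata, m))
    for name, b in beta.items():
        if name in cols:
            eta += b * cols[name]
    w = np.exp(eta - eta.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random((n_strata, 1))
    choice = (w.cumsum(axis=1) < u).sum(axis=1)
    case = np.zeros((n_strata, m), dtype=int)
    case[np.arange(n_strata), choice] = 1
    out = pd.DataFrame({
        "stratum": np.repeat(np.arange(n_strata), m),
        "individual": np.repeat([f"ind_{i % n_individuals:02d}" for i in range(n_strata)], m),
        "case": case.ravel(),
    })
    for name, arr in cols.items():
        out[name] = arr.ravel()
    return out


def occupied_snow_fraction(trackset: TrackSet, snow: EnvRasterSeries,
                           radius_km: float | None = None) -> float:
    """Mean snow cover at the fixes of a track set (lag-0 occupancy).

    With ``radius_km`` the value per fix is the mean over grid cells
    within that great-circle radius (the neighbourhood scale over which
    occupancy phenotypes are measured is a free parameter here);
    otherwise the nearest cell is used.
    """
    vals = []
    if radius_km is None:
        for tr in trackset:
            f = tr.fixes
            v = snow.value_at(f["lon"].to_numpy(), f["lat"].to_numpy(),
                              _as_day(f["timestamp"].dt.tz_localize(None)))
            vals.append(v)
    else:
        glon, glat = np.meshgrid(snow.lons, snow.lats)
        for tr in trackset:
            f = tr.fixes
            d = _as_day(f["timestamp"].dt.tz_localize(None))
            ti = ((d - snow.dates[0]) / DAY).astype(int)
            for lon, lat, t in zip(f["lon"], f["lat"], ti):
                if not (0 <= t < snow.dates.size):
                    continue
                mask = geo.haversine_km(glon, glat, lon, lat) <= radius_km
                if mask.any():
                    vals.append([snow.data.values[t][mask].mean()])
    allv = np.concatenate(vals) if vals else np.array([np.nan])
    return float(np.nanmean(allv))
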