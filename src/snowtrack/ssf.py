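"""Step-selection strata: movement kernel fitting, alternative-step
sampling, and covariate annotation of chosen + alternative endpoints.

Each observed step with a defined previous heading becomes one stratum:
the chosen endpoint plus K (default 10) alternatives drawn from the same
start fix, distance ~ Exponential(rate fitted to observed step lengths)
and absolute bearing = previous heading + a draw (with replacement) from
the empirical turn-angle sample.  All endpoints are annotated with snow
cover on the arrival date and, at the one-day scale, wind support and
crosswind computed from the decision-date wind at the start fix along
each endpoint's own bearing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .enviro import _as_day, wind_decompose
from .tracks import Burst, Step, step_geometry

log = logging.getLogger(__name__)

DEFAULT_K = 10
REDRAW_CAP = 100


@dataclass
class StepDistribution:
    """Movement kernel: exponential distance rate (1/km, MLE = 1/mean
    observed step length) plus the empirical turn-angle sample (deg)."""

    rate_per_km: float
    turn_angles_deg: np.ndarray

    def __post_init__(self):
        if not self.rate_per_km > 0:
            raise ValueError("exponential rate must be > 0")
        self.turn_angles_deg = np.asarray(self.turn_angles_deg, dtype=float)
        if self.turn_angles_deg.size == 0:
            raise ValueError("turn-angle sample is empty")

    @property
    def mean_step_km(self):
        return 1.0 / self.rate_per_km


def fit_step_distribution(steps: list[Step]) -> StepDistribution:
    """Fit the exponential distance kernel and collect turn angles."""
    lengths = np.array([s.length_km for s in steps], dtype=float)
    if lengths.size < 5:
        raise ValueError("need >= 5 steps to fit the step distribution")
    mean = lengths.mean()
    if mean <= 0:
        raise ValueError("all step lengths are zero; cannot fit an exponential")
    turns = np.array([s.turn_deg for s in steps if s.turn_deg is not None], dtype=float)
    if turns.size == 0:
        raise ValueError("no steps with a defined turn angle")
    return StepDistribution(rate_per_km=1.0 / mean, turn_angles_deg=turns)


def sample_alternatives(step: Step, dist: StepDistribution, K: int, seed) -> np.ndarray:
    """Draw K alternative endpoints for one chosen step.

    Distances ~ Exponential(dist.rate); bearing = the step's previous
    heading + an empirical turn-angle draw.  ``seed`` may be an int or a
    ``numpy.random.Generator``.  Returns an array of shape (K, 2) of
    (lon, lat).  Raises if the step has no previous heading.
    """
    if step.turn_deg is None:
        raise ValueError("step has no previous heading; cannot sample alternatives")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prev_heading = (step.heading_deg - step.turn_deg) % 360.0
    d = rng.exponential(dist.mean_step_km, size=K)
    bearings = (prev_heading + rng.choice(dist.turn_angles_deg, size=K, replace=True)) % 360.0
    lon, lat = geo.destination(step.lon0, step.lat0, bearings, d)
    return np.column_stack([lon, lat])


def endpoint_covariates(start_lon, start_lat, date0, date1, end_lons, end_lats,
                        series_map: dict, include_wind: bool = True) -> pd.DataFrame:
    """Covariates for candidate endpoints sharing one start fix.

    snow: nearest-cell snow at the endpoint on the arrival date ``date1``.
    wind support / crosswind: the decision-date (``date0``) wind sampled
    at the *start* fix, decomposed along each start->endpoint bearing, so
    candidates within a stratum differ only through their bearing.
    """
    end_lons = np.asarray(end_lons, dtype=float)
    end_lats = np.asarray(end_lats, dtype=float)
    out = {}
    if "snow" in series_map:
        out["snow"] = series_map["snow"].value_at(end_lons, end_lats, np.repeat(_as_day(date1), end_lons.size))
    if include_wind and "wind_u" in series_map and "wind_v" in series_map:
        u = series_map["wind_u"].value_at(start_lon, start_lat, date0)[0]
        v = series_map["wind_v"].value_at(start_lon, start_lat, date0)[0]
        bearing = geo.initial_bearing_deg(start_lon, start_lat, end_lons, end_lats)
        ws, cw = wind_decompose(u, v, bearing)
        out["wind_support"] = ws
        out["crosswind"] = cw
    return pd.DataFrame(out)


def build_strata(bursts: list[Burst], series_map: dict, K: int = DEFAULT_K,
                 seed: int = 0, include_wind: bool = True,
                 dist: StepDistribution | None = None) -> pd.DataFrame:
    """Build annotated SSF strata from resampled bursts.

    One stratum per chosen step with a previous heading (the first step
    of each burst only seeds the turn-angle reference).  Alternatives
    falling off the snow grid are redrawn up to 100 times; strata that
    still lack valid endpoints, or whose chosen endpoint annotates as
    missing, are dropped and counted.

    Returns a long-format frame with columns: stratum, individual, year,
    date, case (1 chosen / 0 alternative), lon, lat, start_lon,
    start_lat, plus the covariate columns.
    """
    rng = np.random.default_rng(seed)
    all_steps = [s for b in bursts for s in step_geometry(b)]
    if dist is None:
        dist = fit_step_distribution(all_steps)
    snow = series_map.get("snow")

    rows = []
    stratum_id = 0
    n_skipped_no_heading = 0
    n_dropped = 0
    for b in bursts:
        for s in step_geometry(b):
            if s.turn_deg is None:
                n_skipped_no_heading += 1
                continue
            date0 = _as_day(s.t0)
            date1 = _as_day(s.t1)
            # redraw alternatives landing off-grid; drop the stratum at the cap
            alts = sample_alternatives(s, dist, K, rng)
            if snow is not None:
                for _ in range(REDRAW_CAP):
                    bad = ~snow.in_bounds(alts[:, 0], alts[:, 1])
                    if not bad.any():
                        break
                    alts[bad] = sample_alternatives(s, dist, int(bad.sum()), rng)
                else:
                    n_dropped += 1
                    continue
                if not snow.in_bounds(s.lon1, s.lat1):
                    n_dropped += 1
                    continue
            lons = np.concatenate([[s.lon1], alts[:, 0]])
            lats = np.concatenate([[s.lat1], alts[:, 1]])
            cov = endpoint_covariates(s.lon0, s.lat0, date0, date1, lons, lats,
                                      series_map, include_wind=include_wind)
            if cov.iloc[0].isna().any():
                n_dropped += 1
                continue
            block = pd.DataFrame({
                "stratum": stratum_id, "individual": s.individual, "year": s.year,
                "date": np.repeat(date0, K + 1),
                "case": np.concatenate([[1], np.zeros(K, dtype=int)]).astype(int),
                "lon": lons, "lat": lats,
                "start_lon": s.lon0, "start_lat": s.lat0,
            })
            rows.append(pd.concat([block, cov], axis=1))
            stratum_id += 1
    if n_skipped_no_heading or n_dropped:
        log.info("build_strata: %d strata built; %d first-steps skipped (no heading); "
                 "%d strata dropped (off-grid/missing)", stratum_id, n_skipped_no_heading, n_dropped)
    if not rows:
        return pd.DataFrame(columns=["stratum", "individual", "year", "date", "case",
                                     "lon", "lat", "start_lon", "start_lat"])
    return pd.concat(rows, ignore_index=True)
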