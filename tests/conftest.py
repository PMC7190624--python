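import warnings

import numpy as np
import pandas as pd
import pytest

from snowtrack import simulate
from snowtrack.tracks import Track


@pytest.fixture(scope="session")
def front_cfg():
    """Deterministic (noise-free) melt front over a compact spring window."""
    return simulate.SnowFrontConfig(
        lon_min=20.0, lon_max=36.0, lat_min=55.0, lat_max=75.0, cell_deg=0.25,
        date_start="2016-03-01", date_end="2016-06-30",
        front_start_lat=58.0, front_speed_deg_per_day=0.15,
        melt_steepness=1.5, noise_prob=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def world(front_cfg):
    """Shared raster stack: snow + temperature/NDVI/wind on one grid."""
    rasters = {"snow": simulate.make_snow_series(front_cfg)}
    rasters.update(simulate.make_env_fields(front_cfg))
    return rasters


@pytest.fixture(scope="session")
def mode_sims(front_cfg, world):
    """One simulation per melt-front coupling mode, shared across tests."""
    sims = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, mode in enumerate(simulate.COUPLING_MODES):
            cfg = simulate.AgentConfig(
                n_individuals=8, n_steps=30, coupling=mode,
                beta={"snow": -1.0, "wind_support": 0.05, "crosswind": 0.0},
                seed=11 + i,
            )
            sims[mode] = simulate.simulate_agents(cfg, world, front_cfg)
    return sims


def make_track(lats, lons=None, start="2016-04-01", freq="D", individual="bird",
               sensor="gps"):
    """Build a Track from latitude (and optional longitude) sequences."""
    lats = np.asarray(lats, dtype=float)
    lons = np.full_like(lats, 20.0) if lons is None else np.asarray(lons, dtype=float)
    ts = pd.date_range(start, periods=lats.size, freq=freq, tz="UTC")
    df = pd.DataFrame({"individual": individual, "timestamp": ts,
                       "lon": lons, "lat": lats, "sensor": sensor,
                       "argos_class": np.nan})
    return Track(individual, int(ts[0].year), df)
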