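"""Daily environmental raster series and track annotation.

A raster series is a date-indexed stack of regular lon/lat grids for one
variable (binary snow cover, air temperature, NDVI, or wind U/V).  Tracks
are annotated by nearest-cell lookup on the fix's own calendar date;
additional utilities compute astronomical day length, decompose wind into
support/crosswind along a heading, and build the +/-10-day lag table used
by the snowmelt-tracking analysis.

Design notes
------------
* Nearest-neighbour lookup only, no bilinear interpolation: the snow
  variable is binary, and the continuous variables use the same rule for
  consistency.  Equidistant ties break toward the lower grid index.
* A point counts as inside the grid if it lies within half a cell of the
  outermost cell centres; anything beyond that, or dated outside the
  series, annotates as missing (NaN) and is counted in the log.
* The wind convention is meteorological U/V: u eastward, v northward, m/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

log = logging.getLogger(__name__)

DAY = np.timedelta64(1, "D")


def _as_day(dates):
    """Coerce scalars/arrays of datetime-like values to datetime64[D]."""
    return np.asarray(pd.to_datetime(dates).to_numpy() if not isinstance(dates, np.ndarray) else dates,
                      dtype="datetime64[D]")


@dataclass
class EnvRasterSeries:
    """One environmental variable on a daily regular lon/lat grid.

    Wraps an ``xarray.DataArray`` with dims ``(date, lat, lon)``.  Axes
    must be strictly increasing and the date axis daily without gaps.
    """

    name: str
    data: xr.DataArray = field(repr=False)

    def __post_init__(self):
        if tuple(self.data.dims) != ("date", "lat", "lon"):
            raise ValueError(f"raster dims must be (date, lat, lon), got {self.data.dims}")
        for ax in ("lat", "lon"):
            v = self.data[ax].values
            if v.size == 0:
                raise ValueError(f"degenerate grid: empty {ax} axis")
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValueError(f"{ax} axis must be strictly increasing")
        d = _as_day(self.data["date"].values)
        if d.size == 0:
            raise ValueError("empty date axis")
        if d.size > 1 and not np.all(np.diff(d) == DAY):
            raise ValueError("date axis must be daily with no gaps")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_arrays(cls, name, dates, lats, lons, values):
        dates = _as_day(dates)
        da = xr.DataArray(
            np.asarray(values),
            coords={"date": dates, "lat": np.asarray(lats, dtype=float),
                    "lon": np.asarray(lons, dtype=float)},
            dims=("date", "lat", "lon"),
            name=name,
        )
        return cls(name, da)

    @classmethod
    def from_netcdf(cls, path, name=None):
        ds = xr.open_dataset(path, engine="scipy")
        if name is None:
            name = list(ds.data_vars)[0]
        return cls(name, ds[name].load())

    def to_netcdf(self, path):
        # scipy engine writes NetCDF3 and needs no external library
        self.data.to_dataset(name=self.name).to_netcdf(path, engine="scipy")

    # -- axes ---------------------------------------------------------

    @property
    def dates(self):
        return _as_day(self.data["date"].values)

    @property
    def lats(self):
        return self.data["lat"].values

    @property
    def lons(self):
        return self.data["lon"].values

    @property
    def cell_deg(self):
        lons = self.lons
        lats = self.lats
        if lons.size > 1:
            return float(lons[1] - lons[0])
        if lats.size > 1:
            return float(lats[1] - lats[0])
        return 1.0

    # -- lookup -------------------------------------------------------

    @staticmethod
    def _nearest_idx(axis, v):
        """Index of the nearest axis value; equidistant ties -> lower index."""
        v = np.asarray(v, dtype=float)
        i = np.clip(np.searchsorted(axis, v), 1, axis.size - 1) if axis.size > 1 else np.zeros(v.shape, dtype=int)
        if axis.size == 1:
            return i
        left = axis[i - 1]
        right = axis[i]
        return np.where((v - left) <= (right - v), i - 1, i)

    def in_bounds(self, lon, lat):
        half = self.cell_deg / 2.0
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return ((lon >= self.lons[0] - half) & (lon <= self.lons[-1] + half)
                & (lat >= self.lats[0] - half) & (lat <= self.lats[-1] + half))

    def value_at(self, lon, lat, date):
        """Nearest-cell value at (lon, lat) on the given calendar date(s).

        Out-of-grid points and out-of-range dates return NaN.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        date = np.atleast_1d(_as_day(date))
        lon, lat, date = np.broadcast_arrays(lon, lat, date)
        ti = ((date - self.dates[0]) / DAY).astype(int)
        ok = self.in_bounds(lon, lat) & (ti >= 0) & (ti < self.dates.size)
        out = np.full(lon.shape, np.nan)
        if ok.any():
            yi = self._nearest_idx(self.lats, lat[ok])
            xi = self._nearest_idx(self.lons, lon[ok])
            out[ok] = self.data.values[ti[ok], yi, xi]
        return out


def annotate(points: pd.DataFrame, series: EnvRasterSeries, column: str | None = None) -> pd.DataFrame:
    """Annotate points with the raster value on each point's own date.

    ``points`` needs columns ``lon``, ``lat``, ``date``.  Returns a copy
    with one added column (named after the series); missing annotations
    (off-grid or off-range) are NaN and their count is logged.
    """
    out = points.copy()
    vals = series.value_at(out["lon"].to_numpy(), out["lat"].to_numpy(), out["date"])
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        log.warning("annotate(%s): %d of %d points missing (off grid or date range)",
                    series.name, n_missing, len(out))
    out[column or series.name] = vals
    return out


def day_length(lat, date):
    """Astronomical day length in hours (CBM model of Forsythe et al.).

    Daylight is defined by the sun's centre crossing the horizon; polar
    day returns 24 h and polar night 0 h.  ``date`` may be datetime-like
    or an integer day of year; both arguments broadcast.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.issubdtype(np.asarray(date).dtype, np.number):
        doy = np.asarray(date, dtype=float)
    else:
        d = pd.to_datetime(np.atleast_1d(date))
        doy = np.asarray(d.dayofyear, dtype=float)
        if np.ndim(date) == 0:
            doy = doy[0]
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    latr = np.radians(lat)
    x = np.sin(latr) * np.sin(phi) / (np.cos(latr) * np.cos(phi))
    return 24.0 - (24.0 / np.pi) * np.arccos(np.clip(x, -1.0, 1.0))


def wind_decompose(u, v, heading_deg):
    """Split a wind vector into support and crosswind along a heading.

    support   = u * sin(h) + v * cos(h)   (positive = tailwind)
    crosswind = u * cos(h) - v * sin(h)   (signed perpendicular component)

    NaN headings (zero-length steps) yield NaN components.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    h = np.radians(np.asarray(heading_deg, dtype=float))
    support = u * np.sin(h) + v * np.cos(h)
    crosswind = u * np.cos(h) - v * np.sin(h)
    return support, crosswind


LAGS_DEFAULT = tuple(range(-10, 11))


def lag_extract(points: pd.DataFrame, series_map: dict, lags=LAGS_DEFAULT,
                include_day_length: bool = True) -> pd.DataFrame:
    """Build the lag table: location held fixed, the date shifted by tau.

    For every point and every lag tau (default -10..+10 days) the raster
    value at the point's *fixed* location on ``date + tau`` is extracted,
    one long-format row per point x lag x variable.  Day length, when
    requested, is recomputed for the shifted date at the fixed latitude.
    Shifted dates outside a series' range are kept but flagged missing.

    ``points`` needs ``lon``, ``lat``, ``date`` and, if present,
    ``individual``/``year`` are carried through; a ``loc_id`` column is
    generated when absent.
    """
    pts = points.reset_index(drop=True).copy()
    if "loc_id" not in pts.columns:
        pts["loc_id"] = np.arange(len(pts))
    base_cols = [c for c in ("individual", "year", "loc_id", "lon", "lat", "date") if c in pts.columns]
    dates0 = _as_day(pts["date"])
    lon = pts["lon"].to_numpy()
    lat = pts["lat"].to_numpy()

    frames = []
    for tau in lags:
        shifted = dates0 + int(tau) * DAY
        block_base = pts[base_cols].copy()
        block_base["lag"] = int(tau)
        for name, series in series_map.items():
            block = block_base.copy()
            block["variable"] = name
            block["value"] = series.value_at(lon, lat, shifted)
            frames.append(block)
        if include_day_length:
            block = block_base.copy()
            block["variable"] = "day_length"
            block["value"] = day_length(lat, shifted)
            frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    table["missing"] = table["value"].isna()
    n_missing = int(table["missing"].sum())
    if n_missing:
        log.warning("lag_extract: %d of %d rows missing (shifted date off range or off grid)",
                    n_missing, len(table))
    return table
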