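"""Movement-track ingestion, quality filtering, resampling and step geometry.

Input is Movebank-style delimited text with the columns
``individual-local-identifier``, ``timestamp``, ``location-long``,
``location-lat`` and optionally ``sensor-type`` and ``argos-lc``.
Tracks are split per individual and calendar year; Argos fixes are
filtered by location class (GPS fixes pass through untouched); tracks are
resampled into fixed-interval bursts from which step lengths, headings
and turn angles are derived on a 6371-km sphere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual-local-identifier", "timestamp", "location-long", "location-lat")

#: CLS Argos location classes, best to worst.
ARGOS_CLASS_ORDER = ("3", "2", "1", "0", "A", "B", "Z")
_CLASS_RANK = {c: len(ARGOS_CLASS_ORDER) - i for i, c in enumerate(ARGOS_CLASS_ORDER)}


@dataclass
class Track:
    """Ordered fixes for one individual-year.

    ``fixes`` has columns individual, timestamp (UTC), lon, lat, sensor,
    argos_class; timestamps strictly increase.
    """

    individual: str
    year: int
    fixes: pd.DataFrame = field(repr=False)

    def __len__(self):
        return len(self.fixes)

    @property
    def times_days(self):
        """Elapsed time of each fix in days since the first fix."""
        t = self.fixes["timestamp"]
        return (t - t.iloc[0]).dt.total_seconds().to_numpy() / 86400.0


@dataclass
class TrackSet:
    tracks: list[Track]
    dropped_rows: int = 0

    def __len__(self):
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def n_fixes(self):
        return sum(len(t) for t in self.tracks)


@dataclass
class Burst:
    """Gap-free resampled segment: fixes ~step_days apart."""

    individual: str
    year: int
    burst_id: int
    step_days: float
    fixes: pd.DataFrame = field(repr=False)

    def __len__(self):
        return len(self.fixes)


@dataclass
class Step:
    individual: str
    year: int
    burst_id: int
    step_index: int
    t0: pd.Timestamp
    t1: pd.Timestamp
    lon0: float
    lat0: float
    lon1: float
    lat1: float
    length_km: float
    heading_deg: float
    turn_deg: float | None  # None for the first step of a burst
    flagged: bool = False   # heading carried over a zero-length step


def read_tracks(path) -> TrackSet:
    """Read a Movebank-style CSV into one Track per individual-year.

    Rows with unparseable coordinates or timestamps are dropped (count
    logged); exact duplicate individual+timestamp rows keep the first.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"empty track file: {path}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    n_in = len(df)
    out = pd.DataFrame({
        "individual": df["individual-local-identifier"].astype(str),
        "timestamp": pd.to_datetime(df["timestamp"], errors="coerce", utc=True),
        "lon": pd.to_numeric(df["location-long"], errors="coerce"),
        "lat": pd.to_numeric(df["location-lat"], errors="coerce"),
        "sensor": df.get("sensor-type", pd.Series("gps", index=df.index)).fillna("gps").str.lower(),
        "argos_class": df.get("argos-lc", pd.Series(np.nan, index=df.index)),
    })
    out = out.dropna(subset=["timestamp", "lon", "lat"])
    out = out[(out["lat"].between(-90, 90)) & (out["lon"] >= -180) & (out["lon"] < 180)]
    out = out.sort_values(["individual", "timestamp"], kind="mergesort")
    out = out.drop_duplicates(subset=["individual", "timestamp"], keep="first")
    dropped = n_in - len(out)
    if dropped:
        log.info("read_tracks: dropped %d of %d rows (bad parse or duplicate timestamp)", dropped, n_in)
    tracks = []
    for (ind, year), g in out.groupby([out["individual"], out["timestamp"].dt.year], sort=True):
        tracks.append(Track(str(ind), int(year), g.reset_index(drop=True)))
    return TrackSet(tracks, dropped_rows=dropped)


def filter_quality(trackset: TrackSet, min_argos_class: str = "2") -> TrackSet:
    """Drop Argos fixes with location class worse than ``min_argos_class``.

    The class ordering is 3 > 2 > 1 > 0 > A > B > Z; the default keeps
    classes 3 and 2 (error < 500 m).  GPS fixes are never filtered.
    Tracks left with fewer than 3 fixes are dropped with a warning.
    """
    if min_argos_class not in _CLASS_RANK:
        raise ValueError(f"unknown Argos class {min_argos_class!r}")
    min_rank = _CLASS_RANK[min_argos_class]
    kept = []
    dropped_fixes = 0
    for tr in trackset:
        f = tr.fixes
        is_argos = f["sensor"].str.contains("argos", case=False, na=False)
        rank = f["argos_class"].map(_CLASS_RANK).fillna(0)
        keep = (~is_argos) | (rank >= min_rank)
        dropped_fixes += int((~keep).sum())
        f2 = f[keep].reset_index(drop=True)
        if len(f2) < 3:
            warnings.warn(f"track {tr.individual}/{tr.year} dropped: "
                          f"{len(f2)} fixes left after Argos filtering", stacklevel=2)
            continue
        kept.append(Track(tr.individual, tr.year, f2))
    log.info("filter_quality: removed %d Argos fixes below class %s; %d of %d tracks kept",
             dropped_fixes, min_argos_class, len(kept), len(trackset))
    return TrackSet(kept, dropped_rows=trackset.dropped_rows + dropped_fixes)


def resample_steps(track: Track, step_days: float, tolerance_days: float | None = None) -> list[Burst]:
    """Resample a track into bursts of fixes ~``step_days`` apart.

    Greedy forward scan from an anchor fix: fixes closer than
    ``step_days - tolerance`` to the last kept fix are removed; the first
    fix within ``[step_days - tol, step_days + tol]`` joins the current
    burst; a fix beyond ``step_days + tol`` closes the burst and anchors
    a new one.  Default tolerance is 10% of the step length.
    """
    if tolerance_days is None:
        tolerance_days = 0.1 * step_days
    if tolerance_days < 0:
        raise ValueError("tolerance_days must be >= 0")
    t = track.times_days
    n = len(t)
    bursts_idx: list[list[int]] = []
    if n == 0:
        return []
    cur = [0]
    lo = step_days - tolerance_days
    hi = step_days + tolerance_days
    i = 1
    while i < n:
        dt = t[i] - t[cur[-1]]
        if dt < lo:
            i += 1  # too close: remove this fix
        elif dt <= hi:
            cur.append(i)
            i += 1
        else:
            bursts_idx.append(cur)
            cur = [i]
            i += 1
    bursts_idx.append(cur)
    bursts = []
    bid = 0
    for idx in bursts_idx:
        if len(idx) < 2:  # singleton bursts carry no step
            continue
        bursts.append(Burst(track.individual, track.year, bid, step_days,
                            track.fixes.iloc[idx].reset_index(drop=True)))
        bid += 1
    return bursts


def step_geometry(burst: Burst) -> list[Step]:
    """Steps of a burst: haversine length, initial bearing, turn angle.

    Turn angle is defined from the second step on.  A zero-length step
    carries the previous step's heading and is flagged.
    """
    f = burst.fixes
    if len(f) < 2:
        raise ValueError("burst needs >= 2 fixes for steps")
    lon = f["lon"].to_numpy()
    lat = f["lat"].to_numpy()
    steps: list[Step] = []
    prev_heading = None
    for i in range(len(f) - 1):
        length = float(geo.haversine_km(lon[i], lat[i], lon[i + 1], lat[i + 1]))
        flagged = False
        if length == 0.0 and prev_heading is not None:
            heading = prev_heading
            flagged = True
        else:
            heading = float(geo.initial_bearing_deg(lon[i], lat[i], lon[i + 1], lat[i + 1]))
        turn = None if prev_heading is None else float(geo.turn_angle_deg(prev_heading, heading))
        steps.append(Step(burst.individual, burst.year, burst.burst_id, i,
                          f["timestamp"].iloc[i], f["timestamp"].iloc[i + 1],
                          float(lon[i]), float(lat[i]), float(lon[i + 1]), float(lat[i + 1]),
                          length, heading, turn, flagged))
        prev_heading = heading
    return steps


def steps_to_frame(steps: list[Step]) -> pd.DataFrame:
    """Serialise steps to the documented flat CSV layout."""
    return pd.DataFrame([{
        "individual": s.individual, "year": s.year, "burst_id": s.burst_id,
        "step_index": s.step_index, "t0": s.t0, "t1": s.t1,
        "lon0": s.lon0, "lat0": s.lat0, "lon1": s.lon1, "lat1": s.lat1,
        "length_km": s.length_km, "heading_deg": s.heading_deg,
        "turn_deg": np.nan if s.turn_deg is None else s.turn_deg,
    } for s in steps])
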