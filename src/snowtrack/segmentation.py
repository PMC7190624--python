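"""First-passage-time segmentation of spring-migration tracks.

First passage time (FPT) at a fix is the time the trajectory takes to
first move more than a given radius away from that fix, searching
forward along the track with linear interpolation between fixes.  Fast
directed migration shows low FPT; stopovers and residence show high FPT,
so the longest run of sub-threshold FPT inside the spring window is
taken as the migration segment.  When no threshold is supplied it is
placed at the valley between the two modes of the log-FPT distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

from . import geo
from .tracks import Track

SPRING_WINDOW_DEFAULT = (3, 6)  # March .. June inclusive


@dataclass
class FPTProfile:
    radius_km: float
    fpt_days: np.ndarray          # NaN where the circle is never exited
    threshold_days: float | None = None

    @property
    def defined(self):
        return ~np.isnan(self.fpt_days)


def first_passage_time(track: Track, radius_km: float) -> FPTProfile:
    """Forward FPT (days) of every fix for the given radius.

    The trajectory is linearly interpolated between fixes: within the
    segment where the distance-from-anchor first exceeds the radius, the
    crossing time is interpolated in distance.  Fixes whose remaining
    trajectory never leaves the circle have undefined (NaN) FPT.
    """
    if radius_km <= 0:
        raise ValueError("radius must be > 0")
    if len(track) < 3:
        raise ValueError("need >= 3 fixes for an FPT profile")
    lon = track.fixes["lon"].to_numpy()
    lat = track.fixes["lat"].to_numpy()
    t = track.times_days
    n = len(t)
    fpt = np.full(n, np.nan)
    for i in range(n):
        d = geo.haversine_km(lon[i], lat[i], lon[i:], lat[i:])
        above = np.nonzero(d > radius_km)[0]
        if above.size == 0:
            continue
        j = above[0]           # first fix beyond the radius (j >= 1: d[0] = 0)
        d0, d1 = d[j - 1], d[j]
        t0, t1 = t[i + j - 1], t[i + j]
        frac = (radius_km - d0) / (d1 - d0) if d1 > d0 else 0.0
        fpt[i] = (t0 + frac * (t1 - t0)) - t[i]
    if np.all(np.isnan(fpt)):
        warnings.warn(f"FPT undefined at every fix (radius {radius_km} km exceeds track extent)",
                      stacklevel=2)
    return FPTProfile(radius_km, fpt)


def bimodal_threshold(values: np.ndarray) -> float:
    """Valley of a (log-scaled) bimodal sample via KDE.

    Returns the minimum-density point between the two highest KDE modes;
    falls back to the sample median when the density is unimodal or the
    sample is degenerate.
    """
    v = np.log10(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size < 4 or np.ptp(v) < 1e-9:
        return float(10 ** np.median(v)) if v.size else np.nan
    grid = np.linspace(v.min(), v.max(), 256)
    dens = stats.gaussian_kde(v)(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if dens[0] > dens[1]:
        maxima = np.r_[0, maxima]
    if dens[-1] > dens[-2]:
        maxima = np.r_[maxima, dens.size - 1]
    if maxima.size < 2:
        return float(10 ** np.median(v))
    top2 = maxima[np.argsort(dens[maxima])][-2:]
    a, b = sorted(top2)
    valley = grid[a + np.argmin(dens[a:b + 1])]
    return float(10 ** valley)


def extract_migration(track: Track, fpt_profile: FPTProfile,
                      fpt_threshold_days: float | None = None,
                      spring_window: tuple = SPRING_WINDOW_DEFAULT):
    """Longest run of low-FPT fixes within the spring window.

    Returns ``(segment_track, start_date, end_date)``; the segment is
    empty (None) when no fix is below threshold, with a warning.  The
    threshold defaults to the log-FPT bimodality valley of this profile.
    """
    fpt = fpt_profile.fpt_days
    if fpt_threshold_days is None:
        defined = fpt[np.isfinite(fpt)]
        fpt_threshold_days = bimodal_threshold(defined) if defined.size else np.nan
    fpt_profile.threshold_days = fpt_threshold_days
    months = track.fixes["timestamp"].dt.month.to_numpy()
    in_window = (months >= spring_window[0]) & (months <= spring_window[1])
    low = np.where(np.isfinite(fpt), fpt < fpt_threshold_days, False) & in_window
    if not low.any():
        warnings.warn(f"no sub-threshold FPT run in track {track.individual}/{track.year}",
                      stacklevel=2)
        return None, None, None
    # longest contiguous True run
    padded = np.r_[False, low, False].astype(int)
    starts = np.nonzero(np.diff(padded) == 1)[0]
    ends = np.nonzero(np.diff(padded) == -1)[0]
    k = int(np.argmax(ends - starts))
    i0, i1 = starts[k], ends[k]  # half-open
    seg = Track(track.individual, track.year, track.fixes.iloc[i0:i1].reset_index(drop=True))
    return seg, seg.fixes["timestamp"].iloc[0], seg.fixes["timestamp"].iloc[-1]


def segment_summary(segments) -> pd.DataFrame:
    """Flat table of extracted segment boundaries for CSV export."""
    rows = []
    for seg, start, end in segments:
        if seg is None:
            continue
        rows.append({"individual": seg.individual, "year": seg.year,
                     "start": start, "end": end, "n_fixes": len(seg)})
    return pd.DataFrame(rows)
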