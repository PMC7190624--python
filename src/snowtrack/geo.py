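"""Great-circle geometry on a spherical Earth (R = 6371.0 km).

All functions are vectorised over numpy arrays; longitudes/latitudes in
decimal degrees (WGS84 coordinates treated as spherical), bearings in
degrees clockwise from geographic north.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between two points."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial (forward) bearing from point 1 to point 2, in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination(lon, lat, bearing_deg, distance_km):
    """End point of a great-circle step of given length and initial bearing.

    Returns (lon, lat) with longitude normalised to [-180, 180).
    """
    lon, lat, brg = (np.radians(np.asarray(x, dtype=float)) for x in (lon, lat, bearing_deg))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat) * np.cos(delta) + np.cos(lat) * np.sin(delta) * np.cos(brg))
    lon2 = lon + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat),
        np.cos(delta) - np.sin(lat) * np.sin(lat2),
    )
    lon2 = (np.degrees(lon2) + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def turn_angle_deg(prev_heading, heading):
    """Signed smallest difference heading - prev_heading, in (-180, 180]."""
    d = (np.asarray(heading, dtype=float) - np.asarray(prev_heading, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)
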