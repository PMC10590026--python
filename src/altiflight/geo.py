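"""Great-circle geometry on the WGS84 sphere.

Distances and bearings use the spherical haversine / forward-azimuth
formulas with the WGS84 mean radius.  At foraging-trip scale (tens of
kilometres) the spherical approximation differs from a full geodesic by
well under 0.1%, which is far below GPS positional error.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # WGS84 mean radius

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "initial_bearing_rad",
    "wrap_angle",
    "local_xy_to_lonlat",
    "lonlat_to_local_xy",
]


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Forward azimuth from point 1 to point 2, radians clockwise from north."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(x, y)


def wrap_angle(theta):
    """Wrap an angle (rad) to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def local_xy_to_lonlat(x_m, y_m, lon0: float, lat0: float):
    """Convert local east/north metres around (lon0, lat0) to lon/lat degrees.

    Equirectangular projection centred on the reference point; adequate for
    the < 100 km offsets the simulator produces.
    """
    lat = np.asarray(y_m, dtype=float) / EARTH_RADIUS_M
    lon = np.asarray(x_m, dtype=float) / (EARTH_RADIUS_M * np.cos(np.radians(lat0)))
    return lon0 + np.degrees(lon), lat0 + np.degrees(lat)


def lonlat_to_local_xy(lon, lat, lon0: float, lat0: float):
    """Inverse of :func:`local_xy_to_lonlat`."""
    x = np.radians(np.asarray(lon, dtype=float) - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat, dtype=float) - lat0) * EARTH_RADIUS_M
    return x, y
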