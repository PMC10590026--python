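"""Track cleaning and stratification ahead of behavioural modelling.

The cleaning order matters and mirrors the analysis workflow: trajectory
metrics are computed on the raw per-individual streams, fixes are cut to
foraging trips (outside the colony rectangle), restricted to offshore
water, stripped of platform-roosting points, and finally split into the
two sampling-rate strata that are modelled separately.  Every operation
returns a subset of its input rows (possibly with added columns) — no
fixes are fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from sklearn.mixture import GaussianMixture

from .geo import haversine_m, initial_bearing_rad, wrap_angle


@dataclass
class ColonyRectangle:
    """Axis-aligned lon/lat rectangle around the breeding colony."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("degenerate colony rectangle")

    @classmethod
    def around(cls, lon: float, lat: float, halfwidth_km: tuple[float, float]) -> "ColonyRectangle":
        dlat = halfwidth_km[1] / 111.32
        dlon = halfwidth_km[0] / (111.32 * np.cos(np.radians(lat)))
        return cls(lon - dlon, lon + dlon, lat - dlat, lat + dlat)

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


def trajectory_metrics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Ground speed and signed turning angle from successive fixes.

    Speed at fix *i* is the great-circle distance from fix *i-1* divided by
    the time gap; the turning angle at an interior fix is the signed change
    in great-circle bearing there, wrapped to (-pi, pi].  First (and for
    turns, last) fixes per individual get NaN.  Duplicate or non-increasing
    timestamps within an individual raise.
    """
    out = fixes.copy()
    out["speed_ms"] = np.nan
    out["turn_rad"] = np.nan
    out["gap_s"] = np.nan
    for _, grp in out.groupby("individual_id", sort=False):
        if len(grp) < 3:
            raise ValueError("need at least 3 fixes per individual")
        t = pd.DatetimeIndex(grp["timestamp"]).asi8 / 1e9
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("duplicate or non-increasing timestamps")
        lon = grp["lon"].values
        lat = grp["lat"].values
        dist = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        bearing = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
        speed = dist / dt
        turn = wrap_angle(np.diff(bearing))
        out.loc[grp.index[1:], "speed_ms"] = speed
        out.loc[grp.index[1:], "gap_s"] = dt
        out.loc[grp.index[1:-1], "turn_rad"] = turn
    return out


def segment_trips(fixes: pd.DataFrame, colony_rect: ColonyRectangle) -> pd.DataFrame:
    """Label maximal runs of consecutive fixes outside the colony rectangle.

    Fixes inside the rectangle are dropped; the survivors carry a
    ``trip_id`` that increments per excursion within each individual.
    """
    outside = ~colony_rect.contains(fixes["lon"].values, fixes["lat"].values)
    out = fixes.copy()
    trip_id = np.full(len(out), -1)
    counter = 0
    for _, grp in out.groupby("individual_id", sort=False):
        mask = outside[out.index.get_indexer(grp.index)]
        starts = mask & ~np.r_[False, mask[:-1]]
        ids = np.cumsum(starts)
        local = np.where(mask, ids + counter - 1, -1)
        trip_id[out.index.get_indexer(grp.index)] = local
        counter += int(ids.max()) if len(ids) else 0
    out["trip_id"] = trip_id
    return out[out["trip_id"] >= 0].copy()


def filter_offshore(fixes: pd.DataFrame, land_mask: BaseGeometry) -> pd.DataFrame:
    """Retain fixes over open water (outside the land polygon set)."""
    on_land = shapely.contains_xy(land_mask, fixes["lon"].values, fixes["lat"].values)
    out = fixes[~on_land].copy()
    out["offshore"] = True
    return out


def filter_platforms(
    fixes: pd.DataFrame, platform_points: pd.DataFrame, radius_m: float = 10.0
) -> pd.DataFrame:
    """Drop fixes within ``radius_m`` (great-circle) of any offshore platform.

    Run before the behavioural clustering so birds roosting on structures
    are not mistaken for birds floating on the sea.
    """
    if radius_m < 0:
        raise ValueError("radius must be non-negative")
    if platform_points is None or len(platform_points) == 0:
        return fixes.copy()
    keep = np.ones(len(fixes), dtype=bool)
    for p in platform_points.itertuples():
        d = haversine_m(fixes["lon"].values, fixes["lat"].values, p.lon, p.lat)
        keep &= d > radius_m
    return fixes[keep].copy()


def split_by_rate(
    fixes: pd.DataFrame,
    base_s: float = 300.0,
    burst_s: float = 10.0,
    tolerance_fraction: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Split fixes into base / burst sampling-rate streams by preceding gap.

    A fix joins the stratum whose nominal interval matches its preceding
    time gap within ``tolerance_fraction``; fixes matching neither (e.g.
    the first of a burst run, whose preceding gap is a base gap shared with
    the base stream — still base — or gaps after dropouts) are excluded.
    """
    if not 0 < tolerance_fraction < 0.5:
        raise ValueError("tolerance fraction must lie in (0, 0.5)")
    if "gap_s" not in fixes:
        raise ValueError("run trajectory_metrics first (gap_s missing)")
    gap = fixes["gap_s"].values
    is_base = np.abs(gap - base_s) <= tolerance_fraction * base_s
    is_burst = np.abs(gap - burst_s) <= tolerance_fraction * burst_s
    out = fixes.copy()
    stratum = np.where(is_base, "base", np.where(is_burst, "burst", "none"))
    out["stratum"] = stratum
    return {
        "base": out[out["stratum"] == "base"].copy(),
        "burst": out[out["stratum"] == "burst"].copy(),
    }


def bimodality_screen(
    speeds,
    turns=None,
    min_fixes: int = 50,
    bic_margin: float = 10.0,
    min_low_weight: float = 0.05,
    seed: int = 0,
) -> tuple[bool, str]:
    """Decide whether an individual shows the bimodal speed structure the
    clustering (and hence calibration) needs.

    A 2-component Gaussian mixture must beat a single Gaussian by more than
    ``bic_margin`` BIC points and the slower mode must carry more than
    ``min_low_weight`` of the mass (birds that never float cannot be
    calibrated).  Returns ``(include, reason)``.
    """
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if len(speeds) < min_fixes:
        return False, "insufficient data"
    X = speeds.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=seed).fit(X)
    g2 = GaussianMixture(2, random_state=seed, n_init=3).fit(X)
    if g1.bic(X) - g2.bic(X) <= bic_margin:
        return False, "unimodal speeds"
    low = int(np.argmin(g2.means_.ravel()))
    if g2.weights_[low] <= min_low_weight:
        return False, "no slow (floating) mode"
    return True, "bimodal"
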