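"""Containers for gridded atmospheric fields and tide-gauge series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr


@dataclass
class EnvironmentField:
    """Hourly sea-level pressure / 2-m temperature grid plus a tide series.

    Attributes
    ----------
    grid : xarray.Dataset
        Dimensions ``(time, lat, lon)`` with variables ``msl`` (mbar) and
        ``t2m`` (K).  The time axis is hourly UTC.
    tide : pandas.Series
        Sea-surface height above Chart Datum (m) on a regular 15-min UTC
        index.
    """

    grid: xr.Dataset
    tide: pd.Series

    def __post_init__(self) -> None:
        for var in ("msl", "t2m"):
            if var not in self.grid:
                raise ValueError(f"field grid missing variable {var!r}")
        if not self.tide.index.is_monotonic_increasing:
            raise ValueError("tide series index must be sorted")

    def nearest(self, lon, lat, t) -> tuple[np.ndarray, np.ndarray]:
        """Sea-level pressure (mbar) and temperature (K) at the nearest
        grid node and nearest hourly step — no interpolation.

        Raises ``ValueError`` for queries outside grid coverage (beyond half
        a grid/time step from the outermost node).
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        t = pd.DatetimeIndex(np.atleast_1d(t))

        lons = self.grid["lon"].values
        lats = self.grid["lat"].values
        times = pd.DatetimeIndex(self.grid["time"].values)

        ilon = _nearest_index(lons, lon, "lon")
        ilat = _nearest_index(lats, lat, "lat")
        tnum = t.asi8.astype(float)
        gnum = times.asi8.astype(float)
        it = _nearest_index(gnum, tnum, "time")

        msl = self.grid["msl"].values[it, ilat, ilon]
        t2m = self.grid["t2m"].values[it, ilat, ilon]
        return msl, t2m

    def tide_at(self, t) -> np.ndarray:
        """Tide height above Chart Datum at the nearest 15-min sample."""
        t = pd.DatetimeIndex(np.atleast_1d(t))
        tnum = t.asi8.astype(float)
        gnum = pd.DatetimeIndex(self.tide.index).asi8.astype(float)
        idx = _nearest_index(gnum, tnum, "tide time")
        return self.tide.values[idx]


def _nearest_index(grid_vals: np.ndarray, queries: np.ndarray, name: str) -> np.ndarray:
    """Index of the nearest grid value; error if beyond one grid step outside."""
    order = np.argsort(grid_vals)
    sorted_vals = grid_vals[order]
    pos = np.searchsorted(sorted_vals, queries)
    pos = np.clip(pos, 1, len(sorted_vals) - 1)
    left = sorted_vals[pos - 1]
    right = sorted_vals[pos]
    take_right = (queries - left) > (right - queries)
    idx = np.where(take_right, pos, pos - 1)
    step = np.max(np.diff(sorted_vals)) if len(sorted_vals) > 1 else np.inf
    if np.any(queries < sorted_vals[0] - step) or np.any(queries > sorted_vals[-1] + step):
        raise ValueError(f"query outside field coverage on axis {name!r}")
    return order[idx]
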