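import numpy as np
import pandas as pd
import pytest
import xarray as xr

from altiflight.environment import EnvironmentField


def make_constant_field(
    p0: float = 1013.25,
    temp: float = 288.15,
    lon0: float = -2.5,
    lat0: float = 56.2,
    start: str = "2019-06-01",
    hours: int = 240,
    tide_value: float = 3.0,
) -> EnvironmentField:
    """Spatially/temporally constant field with a flat tide — the simplest
    environment in which altimetry identities hold exactly."""
    times = pd.date_range(start, periods=hours, freq="h")
    lats = np.array([lat0 - 0.5, lat0, lat0 + 0.5])
    lons = np.array([lon0 - 0.5, lon0, lon0 + 0.5])
    shape = (len(times), len(lats), len(lons))
    grid = xr.Dataset(
        {
            "msl": (("time", "lat", "lon"), np.full(shape, p0)),
            "t2m": (("time", "lat", "lon"), np.full(shape, temp)),
        },
        coords={"time": times.values, "lat": lats, "lon": lons},
    )
    tide_index = pd.date_range(start, periods=hours * 4, freq="15min")
    tide = pd.Series(np.full(len(tide_index), tide_value), index=tide_index)
    return EnvironmentField(grid=grid, tide=tide)


@pytest.fixture
def constant_field():
    return make_constant_field()


@pytest.fixture
def quadrant_data():
    """Well-separated clusters in the four speed x |turn| quadrants with
    known generating labels (speeds m/s, |turn| rad)."""
    rng = np.random.default_rng(42)
    clusters = {
        "stopped": ((0.3, 2.5), (0.2, 0.1)),
        "floating": ((0.4, 0.3), (0.2, 0.1)),
        "commuting": ((9.0, 0.3), (0.2, 0.1)),
        "foraging_searching": ((8.0, 2.2), (0.2, 0.1)),
    }
    speeds, turns, labels = [], [], []
    for name, ((ms, mt), (ss, st)) in clusters.items():
        n = 500
        speeds.append(np.abs(rng.normal(ms, ss, n)))
        turns.append(np.abs(rng.normal(mt, st, n)))
        labels += [name] * n
    return np.concatenate(speeds), np.concatenate(turns), np.array(labels)
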