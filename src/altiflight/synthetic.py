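"""Synthetic tracking-study generator with known ground truth.

Emulates a seabird GPS + barometric-altimeter deployment well enough to
exercise every downstream stage of the pipeline:

* 4-state Markov movement (floating / stopped / commuting /
  foraging-searching) with per-state speed and von Mises turning-angle
  structure, producing the bimodal speed/turn signature the behavioural
  clustering expects;
* foraging trips that leave and return to a colony rectangle, with a dual
  sampling schedule (5-min base, 10-s bursts inside geofence polygons);
* a drifting synoptic sea-level-pressure field (AR(1) in time, linear
  gradients in space) sensed by the tag at its true altitude through the
  barometric law, plus an additive sensor bias and per-reading noise;
* heavy-tailed GPS altitude error (Gaussian core + Student-t outliers);
* harmonic tides above Chart Datum.

Every fix carries a truth record (state, true heights, true sea-level
pressure, injected bias) so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Polygon
import shapely

from . import altimetry
from .environment import EnvironmentField
from .geo import local_xy_to_lonlat

STATES = ("floating", "stopped", "commuting", "foraging_searching")
FLIGHT_STATES = ("commuting", "foraging_searching")


def _default_transition() -> np.ndarray:
    # Mean dwell ~ minutes at 1-s resolution; rows sum to 1.
    return np.array(
        [
            [0.9990, 0.0004, 0.0004, 0.0002],
            [0.0005, 0.9985, 0.0005, 0.0005],
            [0.0003, 0.0002, 0.9990, 0.0005],
            [0.0004, 0.0002, 0.0006, 0.9988],
        ]
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated colony-year deployment."""

    colony_lon: float = -2.556
    colony_lat: float = 56.186
    colony_halfwidth_km: tuple[float, float] = (1.5, 1.5)
    start: str = "2019-06-01T00:00:00Z"
    end: str = "2019-06-11T00:00:00Z"
    n_individuals: int = 3

    # movement
    transition: np.ndarray = dc_field(default_factory=_default_transition)
    speed_mean_ms: tuple[float, ...] = (0.3, 0.2, 10.0, 8.0)
    speed_sd_ms: tuple[float, ...] = (0.15, 0.1, 1.5, 1.5)
    turn_kappa: tuple[float, ...] = (2000.0, 0.4, 3000.0, 5.0)
    # per-state altitude: flight states gamma(shape, scale); water states 0
    altitude_gamma: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {"commuting": (2.0, 20.0), "foraging_searching": (2.0, 10.0)}
    )
    initial_state: str = "commuting"
    trip_mean_h: float = 4.0
    rest_mean_h: float = 2.0
    close_trips: bool = True

    # sampling
    base_interval_s: float = 300.0
    burst_interval_s: float = 10.0
    geofences: list[Polygon] = dc_field(default_factory=list)

    # sensors
    gps_noise_sd_m: float = 5.0
    gps_outlier_prob: float = 0.01
    gps_outlier_scale_m: float = 100.0
    gps_outlier_df: float = 2.0
    pressure_bias_mbar: float = 0.0
    pressure_noise_sd_mbar: float = 0.3
    n_pressure_readings: int = 10
    temp_noise_sd_k: float = 0.0

    # synoptic field
    grid_spacing_km: float = 30.0
    max_range_km: float = 120.0
    synoptic_mean_mbar: float = 1013.25
    synoptic_sd_mbar: float = 6.0
    synoptic_rho: float = 0.98
    spatial_gradient_frac: float = 0.25
    temp_mean_k: float = 288.15
    temp_sd_k: float = 1.5

    # tide: (amplitude m, period h, phase rad)
    tide_constituents: list[tuple[float, float, float]] = dc_field(
        default_factory=lambda: [(1.5, 12.4206, 0.0), (0.5, 12.0, 1.0)]
    )
    chart_datum_offset_m: float = 3.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be non-negative")
        for name in ("speed_sd_ms", "gps_noise_sd_m", "pressure_noise_sd_mbar",
                     "synoptic_sd_mbar", "temp_sd_k"):
            val = getattr(self, name)
            if np.any(np.asarray(val) < 0):
                raise ValueError(f"{name} must be non-negative")
        if not self.burst_interval_s < self.base_interval_s:
            raise ValueError("burst interval must be shorter than base interval")
        if not -1.0 < self.synoptic_rho < 1.0:
            raise ValueError("AR(1) autocorrelation must lie in (-1, 1)")
        if self.initial_state not in STATES:
            raise ValueError(f"unknown initial state {self.initial_state!r}")
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.start.tzinfo is not None:
            self.start = self.start.tz_convert("UTC").tz_localize(None)
        if self.end is not None and self.end.tzinfo is not None:
            self.end = self.end.tz_convert("UTC").tz_localize(None)
        if self.end <= self.start:
            raise ValueError("empty study window")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) with marginal sd ``sd`` and lag-1 autocorrelation ``rho``."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def simulate_environment(config: SimConfig, seed: int) -> EnvironmentField:
    """Hourly pressure/temperature grid plus 15-min tide series.

    The pressure anomaly is a shared AR(1) level plus AR(1) east-west and
    north-south gradients, so each node sees the configured marginal sd and
    lag-1 autocorrelation while the field stays smooth in space.
    """
    if config.grid_spacing_km <= 0:
        raise ValueError("grid spacing must be positive")
    rng = np.random.default_rng(seed)

    half_km = config.max_range_km + config.grid_spacing_km
    n_side = max(2, int(np.ceil(2 * half_km / config.grid_spacing_km)) + 1)
    km_axis = (np.arange(n_side) - (n_side - 1) / 2) * config.grid_spacing_km
    lat_axis = config.colony_lat + km_axis / 111.32
    lon_axis = config.colony_lon + km_axis / (111.32 * np.cos(np.radians(config.colony_lat)))

    times = pd.date_range(config.start.floor("h"), config.end.ceil("h"), freq="h")
    nt = len(times)

    level = _ar1(rng, nt, config.synoptic_sd_mbar, config.synoptic_rho)
    grad_sd = config.synoptic_sd_mbar * config.spatial_gradient_frac
    gx = _ar1(rng, nt, grad_sd, config.synoptic_rho)
    gy = _ar1(rng, nt, grad_sd, config.synoptic_rho)
    xn = km_axis / max(km_axis.max(), 1.0)  # normalized -1..1
    msl = (
        config.synoptic_mean_mbar
        + level[:, None, None]
        + gy[:, None, None] * xn[None, :, None]
        + gx[:, None, None] * xn[None, None, :]
    )
    t2m = config.temp_mean_k + _ar1(rng, nt, config.temp_sd_k, config.synoptic_rho)
    t2m = np.broadcast_to(t2m[:, None, None], msl.shape).copy()

    grid = xr.Dataset(
        {
            "msl": (("time", "lat", "lon"), msl),
            "t2m": (("time", "lat", "lon"), t2m),
        },
        coords={"time": times.values, "lat": lat_axis, "lon": lon_axis},
    )

    tide_index = pd.date_range(config.start.floor("D"), config.end.ceil("D"), freq="15min")
    t_h = (tide_index - tide_index[0]).total_seconds().values / 3600.0
    height = np.full(len(tide_index), config.chart_datum_offset_m, dtype=float)
    for amp, period_h, phase in config.tide_constituents:
        height += amp * np.sin(2.0 * np.pi * t_h / period_h + phase)
    tide = pd.Series(height, index=tide_index, name="height_m")

    return EnvironmentField(grid=grid, tide=tide)


def _simulate_states(rng: np.random.Generator, trans: np.ndarray, n: int, s0: int) -> np.ndarray:
    """Markov state sequence of length n at 1-s resolution, run-length form."""
    states = np.empty(n, dtype=np.int8)
    t = 0
    s = s0
    stay = np.diag(trans)
    while t < n:
        p_stay = stay[s]
        if p_stay >= 1.0:
            run = n - t
        else:
            # geometric dwell (>= 1 step) then one transition
            run = 1 + rng.geometric(1.0 - p_stay) - 1
            run = min(run, n - t)
        states[t : t + run] = s
        t += run
        if t < n:
            probs = trans[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(4, p=probs))
    return states


def _simulate_trip_path(
    rng: np.random.Generator, config: SimConfig, n: int, s0: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1-s states and local x/y (m, colony-origin) for one trip of n seconds."""
    states = _simulate_states(rng, config.transition, n, s0)
    kappa = np.asarray(config.turn_kappa)[states]
    dtheta = rng.vonmises(0.0, kappa)
    heading = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(dtheta)
    speed = np.clip(
        rng.normal(np.asarray(config.speed_mean_ms)[states], np.asarray(config.speed_sd_ms)[states]),
        0.0,
        None,
    )
    dx = speed * np.sin(heading)
    dy = speed * np.cos(heading)
    x = np.cumsum(dx)
    y = np.cumsum(dy)
    if config.close_trips and n > 1:
        # close the trip back onto the colony by removing the net drift in
        # proportion to distance travelled: fast (flight) steps absorb the
        # correction, slow (floating/stopped) steps keep their true speeds
        path = np.cumsum(speed)
        frac = path / max(path[-1], 1e-9)
        x = x - frac * x[-1]
        y = y - frac * y[-1]
    return states, x, y


def simulate_tracks(
    config: SimConfig, env: EnvironmentField, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-individual trips and thin onto the sampling schedule.

    Returns ``(fixes, truth)`` aligned row-for-row.  ``fixes`` holds
    individual ID, UTC timestamp, lon/lat; ``truth`` holds the hidden state,
    true heights, true sea-level pressure/temperature at the fix, and the
    schedule stratum implied by the geofences.
    """
    rng = np.random.default_rng(seed)
    total_s = int((config.end - config.start).total_seconds())
    monthly_msl = altimetry.monthly_msl_from_tide(env.tide)

    rows_fix = []
    rows_truth = []
    state_idx = {s: i for i, s in enumerate(STATES)}
    s0 = state_idx[config.initial_state]

    for ind in range(config.n_individuals):
        ind_id = f"bird{ind + 1:02d}"
        x = np.zeros(total_s)
        y = np.zeros(total_s)
        states = np.full(total_s, state_idx["stopped"], dtype=np.int8)
        on_trip = np.zeros(total_s, dtype=bool)

        t = 0
        resting = config.rest_mean_h > 0
        while t < total_s:
            if resting:
                dur = int(rng.exponential(config.rest_mean_h * 3600.0)) + 1
                dur = min(dur, total_s - t)
                # rest at the colony (inside the rectangle; dropped later)
            else:
                if config.trip_mean_h <= 0:
                    raise ValueError("trip_mean_h must be positive")
                if config.rest_mean_h > 0:
                    dur = int(rng.exponential(config.trip_mean_h * 3600.0)) + 60
                else:
                    dur = total_s  # continuous single trip
                dur = min(dur, total_s - t)
                st, tx, ty = _simulate_trip_path(rng, config, dur, s0)
                states[t : t + dur] = st
                x[t : t + dur] = tx
                y[t : t + dur] = ty
                on_trip[t : t + dur] = True
            t += dur
            if config.rest_mean_h > 0:
                resting = not resting

        lon, lat = local_xy_to_lonlat(x, y, config.colony_lon, config.colony_lat)

        # walk the sampling schedule: burst cadence inside geofences
        fix_t = []
        fix_stratum = []
        tcur = 0.0
        prev_gap = config.base_interval_s
        while tcur < total_s:
            i = int(tcur)
            in_fence = any(
                shapely.contains_xy(g, lon[i], lat[i]) for g in config.geofences
            )
            fix_t.append(i)
            fix_stratum.append("burst" if prev_gap == config.burst_interval_s else "base")
            gap = config.burst_interval_s if in_fence else config.base_interval_s
            tcur += gap
            prev_gap = gap
        fix_t = np.asarray(fix_t, dtype=int)

        ts = config.start + pd.to_timedelta(fix_t, unit="s")
        st = states[fix_t]
        alt_surface = np.zeros(len(fix_t))
        for sname in FLIGHT_STATES:
            mask = st == state_idx[sname]
            if mask.any():
                shape, scale = config.altitude_gamma[sname]
                if scale == 0.0 or shape == 0.0:
                    alt_surface[mask] = shape * scale
                else:
                    alt_surface[mask] = rng.gamma(shape, scale, size=int(mask.sum()))

        tide_at_fix = env.tide_at(ts.values)
        months = pd.DatetimeIndex(ts).to_period("M").to_timestamp()
        msl_month = monthly_msl.reindex(months).values
        alt_msl = alt_surface + (tide_at_fix - msl_month)
        p0_true, temp_true = env.nearest(lon[fix_t], lat[fix_t], ts.values)

        rows_fix.append(
            pd.DataFrame(
                {
                    "individual_id": ind_id,
                    "timestamp": ts,
                    "lon": lon[fix_t],
                    "lat": lat[fix_t],
                }
            )
        )
        rows_truth.append(
            pd.DataFrame(
                {
                    "individual_id": ind_id,
                    "timestamp": ts,
                    "state": np.asarray(STATES)[st],
                    "on_trip": on_trip[fix_t],
                    "alt_surface_m": alt_surface,
                    "alt_msl_m": alt_msl,
                    "p0_true_mbar": p0_true,
                    "temp_true_k": temp_true,
                    "stratum": fix_stratum,
                    "bias_mbar": config.pressure_bias_mbar,
                }
            )
        )

    fixes = pd.concat(rows_fix, ignore_index=True)
    truth = pd.concat(rows_truth, ignore_index=True)
    return fixes, truth


def simulate_sensors(
    fixes: pd.DataFrame,
    truth: pd.DataFrame,
    env: EnvironmentField,
    config: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Attach tag pressure (mbar), tag temperature (K) and GPS altitude (m).

    Tag pressure is the mean of ``n_pressure_readings`` noisy samples of the
    barometric pressure at the bird's true altitude above the sea surface,
    plus the configured constant sensor bias.  GPS altitude is the true
    MSL-referenced altitude plus Gaussian noise and an occasional
    heavy-tailed (Student-t) outlier.
    """
    rng = np.random.default_rng(seed)
    n = len(fixes)
    if n != len(truth):
        raise ValueError("fixes and truth must align")

    p_true = altimetry.pressure_at_altitude(
        truth["alt_surface_m"].values,
        truth["p0_true_mbar"].values,
        truth["temp_true_k"].values,
    )
    k = config.n_pressure_readings
    if config.pressure_noise_sd_mbar > 0:
        burst_noise = rng.normal(0.0, config.pressure_noise_sd_mbar, size=(n, k)).mean(axis=1)
    else:
        burst_noise = np.zeros(n)
    pressure = p_true + burst_noise + config.pressure_bias_mbar

    temp = truth["temp_true_k"].values.copy()
    if config.temp_noise_sd_k > 0:
        temp = temp + rng.normal(0.0, config.temp_noise_sd_k, size=n)

    gps = truth["alt_msl_m"].values + rng.normal(0.0, config.gps_noise_sd_m, size=n)
    if config.gps_outlier_prob > 0:
        hit = rng.random(n) < config.gps_outlier_prob
        gps = gps + hit * rng.standard_t(config.gps_outlier_df, size=n) * config.gps_outlier_scale_m

    out = fixes.copy()
    out["pressure_mbar"] = pressure
    out["temp_k"] = temp
    out["gps_alt_m"] = gps
    return out


def simulate_deployment(
    config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, EnvironmentField]:
    """Environment + tracks + sensors in one call.

    Sub-stage seeds are derived from ``seed`` so identical seeds reproduce
    identical outputs byte-for-byte.
    """
    ss = np.random.SeedSequence(seed)
    s_env, s_trk, s_sen = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    env = simulate_environment(config, s_env)
    fixes, truth = simulate_tracks(config, env, s_trk)
    fixes = simulate_sensors(fixes, truth, env, config, s_sen)
    return fixes, truth, env
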