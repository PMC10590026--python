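"""Barometric altimetry: pressure -> height above the sea surface -> height
above mean sea level.

The conversion chain is

1. ``barometric_altitude`` — isothermal barometric formula
   ``h = (kT / mg) * ln(P0 / P)``, with the tag's own temperature reading
   for ``T``.  (The hypsometric relation is often written with the
   argument order inverted, ``ln(P/P0)``, which yields negative heights
   for pressures below sea level; this module uses ``ln(P0/P)`` so that
   lower pressure aloft gives positive altitude.)
2. Sea-level pressure ``P0`` comes from the nearest node/hour of a gridded
   reanalysis-style field, corrected by an additive offset measured while
   the bird sat on the water ("floating bouts").  Offsets are carried
   forward in time and expire after a staleness limit (default one day).
3. Heights above the instantaneous sea surface are referred to mean sea
   level using a tide-gauge series: ``h_MSL = h_surface + (tide - MSL_month)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import EnvironmentField

# Physical constants for dry air
GAS_CONSTANT = 8.31432  # N m mol^-1 K^-1
MOLAR_MASS_AIR = 0.0289644  # kg mol^-1
GRAVITY = 9.80665  # m s^-2

#: Scale height multiplier kT/mg at T = 288.15 K, ~8434.5 m (sanity anchor)
SCALE_HEIGHT_288 = GAS_CONSTANT * 288.15 / (MOLAR_MASS_AIR * GRAVITY)

#: Calibration offsets larger than this are treated as sensor faults.
MAX_VALID_OFFSET_MBAR = 50.0

DEFAULT_STALENESS_LIMIT_S = 86_400.0  # one day


def barometric_altitude(pressure_mbar, p0_mbar, temperature_k):
    """Height (m) above the P0 reference surface from tag pressure.

    Parameters are broadcast together; all must be strictly positive.
    """
    p = np.asarray(pressure_mbar, dtype=float)
    p0 = np.asarray(p0_mbar, dtype=float)
    t = np.asarray(temperature_k, dtype=float)
    if np.any(p <= 0) or np.any(p0 <= 0):
        raise ValueError("pressures must be positive")
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return (GAS_CONSTANT * t) / (MOLAR_MASS_AIR * GRAVITY) * np.log(p0 / p)


def pressure_at_altitude(h_m, p0_mbar, temperature_k):
    """Inverse of :func:`barometric_altitude`: P = P0 exp(-mgh / kT)."""
    h = np.asarray(h_m, dtype=float)
    p0 = np.asarray(p0_mbar, dtype=float)
    t = np.asarray(temperature_k, dtype=float)
    if np.any(p0 <= 0) or np.any(t <= 0):
        raise ValueError("p0 and temperature must be positive")
    return p0 * np.exp(-(MOLAR_MASS_AIR * GRAVITY * h) / (GAS_CONSTANT * t))


def nearest_field_value(field: EnvironmentField, lon, lat, t):
    """Sea-level pressure (mbar) and temperature (K) at the nearest grid
    node and hourly step.  Thin wrapper kept for pipeline symmetry."""
    return field.nearest(lon, lat, t)


@dataclass
class CalibrationRecord:
    """Additive pressure offset measured over one floating bout."""

    bout_id: int
    individual_id: str
    timestamp: pd.Timestamp  # bout midpoint, UTC
    lon: float
    lat: float
    tag_pressure_mbar: float  # bout-mean surface pressure from the tag
    model_p0_mbar: float  # field value at bout midpoint
    offset_mbar: float  # tag - model
    valid: bool


def derive_calibration_offsets(
    bouts: pd.DataFrame,
    fixes: pd.DataFrame,
    field: EnvironmentField,
    min_fixes: int = 1,
    consistency_mbar: float = 1.0,
) -> list[CalibrationRecord]:
    """One calibration record per floating bout.

    ``bouts`` is the frame from :func:`altiflight.behaviour.floating_bouts`
    (columns ``bout_id``, ``individual_id``, ``start``, ``end``, ``mid``,
    ``fix_index`` with the index labels of member fixes).  The offset is
    the bout median of the per-fix difference between tag pressure and the
    model sea-level pressure at that fix's own nearest cell/hour — pairing
    each surface reading with the model value it will later correct (so a
    synoptic trend across the bout does not leak in), with the median
    guarding against the occasional airborne fix that behavioural
    misclassification sneaks into a bout.  ``min_fixes`` discards bouts
    with fewer usable members (short bouts carry no redundancy).
    """
    records: list[CalibrationRecord] = []
    for row in bouts.itertuples():
        members = fixes.loc[row.fix_index]
        ok = members["pressure_mbar"].notna()
        if not ok.any():
            raise ValueError(f"bout {row.bout_id} has no pressure samples")
        members = members[ok]
        if len(members) < min_fixes:
            continue
        model_at_fix, _ = field.nearest(
            members["lon"].values, members["lat"].values, members["timestamp"].values
        )
        tag_p = float(members["pressure_mbar"].mean())
        model_p0 = float(np.mean(model_at_fix))
        mid_lon = float(members["lon"].median())
        mid_lat = float(members["lat"].median())
        # robust bout offset: altitude can only lower the sensed pressure,
        # so fixes truly on the water form the upper edge of the per-fix
        # (tag - model) differences; airborne fixes that behavioural
        # misclassification sneaks into a bout sit several mbar below it
        diffs = members["pressure_mbar"].values - model_at_fix
        consistent = diffs[diffs >= diffs.max() - consistency_mbar]
        offset = float(np.median(consistent))
        records.append(
            CalibrationRecord(
                bout_id=int(row.bout_id),
                individual_id=str(row.individual_id),
                timestamp=pd.Timestamp(row.mid),
                lon=mid_lon,
                lat=mid_lat,
                tag_pressure_mbar=tag_p,
                model_p0_mbar=model_p0,
                offset_mbar=offset,
                valid=abs(offset) < MAX_VALID_OFFSET_MBAR,
            )
        )
    records.sort(key=lambda r: (r.individual_id, r.timestamp))
    return records


def records_frame(records: list[CalibrationRecord]) -> pd.DataFrame:
    """Calibration records as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "bout_id": [r.bout_id for r in records],
            "individual_id": [r.individual_id for r in records],
            "timestamp": [r.timestamp for r in records],
            "lon": [r.lon for r in records],
            "lat": [r.lat for r in records],
            "tag_pressure_mbar": [r.tag_pressure_mbar for r in records],
            "model_p0_mbar": [r.model_p0_mbar for r in records],
            "offset_mbar": [r.offset_mbar for r in records],
            "valid": [r.valid for r in records],
        }
    )


def calibrated_sea_level_pressure(
    fixes: pd.DataFrame,
    records: list[CalibrationRecord],
    field: EnvironmentField,
    staleness_limit_s: float = DEFAULT_STALENESS_LIMIT_S,
) -> pd.DataFrame:
    """Per-fix calibrated P0 and staleness.

    Returns a frame aligned to ``fixes`` with columns
    ``p0_model_mbar``, ``p0_calibrated_mbar``, ``staleness_s``, ``stale``.
    The offset of the most recent prior valid bout for the same individual
    is carried forward (no interpolation — the correction is stepwise and
    causal); fixes more than ``staleness_limit_s`` after that bout, or
    before the first bout, are flagged stale and get NaN calibrated P0.
    """
    p0_model, _ = field.nearest(
        fixes["lon"].values, fixes["lat"].values, fixes["timestamp"].values
    )
    out = pd.DataFrame(index=fixes.index)
    out["p0_model_mbar"] = p0_model
    out["p0_calibrated_mbar"] = np.nan
    out["staleness_s"] = np.nan
    out["stale"] = True

    by_ind: dict[str, list[CalibrationRecord]] = {}
    for r in records:
        if r.valid:
            by_ind.setdefault(r.individual_id, []).append(r)

    for ind, grp in fixes.groupby("individual_id", sort=False):
        recs = by_ind.get(str(ind), [])
        if not recs:
            continue
        rec_times = np.array([r.timestamp.value for r in recs], dtype="int64")
        offsets = np.array([r.offset_mbar for r in recs])
        t = pd.DatetimeIndex(grp["timestamp"]).asi8
        pos = np.searchsorted(rec_times, t, side="right") - 1
        has_prior = pos >= 0
        staleness = np.full(len(grp), np.nan)
        staleness[has_prior] = (t[has_prior] - rec_times[pos[has_prior]]) / 1e9
        fresh = has_prior & (staleness <= staleness_limit_s)
        out.loc[grp.index, "staleness_s"] = staleness
        out.loc[grp.index[fresh], "stale"] = False
        out.loc[grp.index[fresh], "p0_calibrated_mbar"] = (
            out.loc[grp.index[fresh], "p0_model_mbar"].values + offsets[pos[fresh]]
        )
    return out


def altimeter_heights(
    fixes: pd.DataFrame,
    records: list[CalibrationRecord],
    field: EnvironmentField,
    staleness_limit_s: float = DEFAULT_STALENESS_LIMIT_S,
    use_model_temperature: bool = False,
) -> pd.DataFrame:
    """Per-fix height above the instantaneous sea surface (m).

    Returns ``fixes`` with added columns ``p0_model_mbar``,
    ``p0_calibrated_mbar``, ``staleness_s``, ``stale`` and
    ``height_surface_m`` (NaN where stale).  By default the tag's own
    temperature drives the conversion; ``use_model_temperature`` switches
    to the field's 2-m temperature for sensitivity runs.
    """
    cal = calibrated_sea_level_pressure(fixes, records, field, staleness_limit_s)
    out = fixes.copy()
    for col in cal.columns:
        out[col] = cal[col]
    if use_model_temperature:
        _, temp = field.nearest(
            out["lon"].values, out["lat"].values, out["timestamp"].values
        )
    else:
        temp = out["temp_k"].values
    ok = ~out["stale"].values
    h = np.full(len(out), np.nan)
    if ok.any():
        h[ok] = barometric_altitude(
            out.loc[ok, "pressure_mbar"].values,
            out.loc[ok, "p0_calibrated_mbar"].values,
            np.asarray(temp, dtype=float)[ok],
        )
    out["height_surface_m"] = h
    return out


def monthly_msl_from_tide(tide: pd.Series) -> pd.Series:
    """Monthly mean sea level above Chart Datum: mean of daily mean heights.

    Index of the result is the month start timestamp.  Empty input raises.
    """
    if tide.empty:
        raise ValueError("empty tide series")
    daily = tide.groupby(tide.index.floor("D")).mean()
    monthly = daily.groupby(daily.index.to_period("M")).mean()
    monthly.index = monthly.index.to_timestamp()
    return monthly


def heights_to_msl(
    fixes: pd.DataFrame,
    field: EnvironmentField,
    monthly_msl: pd.Series | None = None,
    height_col: str = "height_surface_m",
) -> pd.DataFrame:
    """Refer surface heights to mean sea level.

    ``h_MSL = h_surface + (tide(t) - MSL_month(t))`` with the tide matched
    to the nearest 15-min gauge sample and MSL the calendar-month value.
    GPS altitudes are already MSL-referenced and pass through untouched.
    """
    if monthly_msl is None:
        monthly_msl = monthly_msl_from_tide(field.tide)
    out = fixes.copy()
    tide = field.tide_at(out["timestamp"].values)
    months = pd.DatetimeIndex(out["timestamp"]).to_period("M").to_timestamp()
    msl = monthly_msl.reindex(months).values
    if np.any(np.isnan(msl)):
        raise ValueError("fix months outside tide-series coverage")
    out["tide_m"] = tide
    out["height_msl_m"] = out[height_col].values + (tide - msl)
    return out


def gps_bias_correction(
    fixes: pd.DataFrame,
    bouts: pd.DataFrame,
    enabled: bool = False,
    min_bout_fixes: int = 20,
) -> pd.DataFrame:
    """Optional per-individual GPS altitude de-biasing.

    Birds sitting on the water should read a GPS altitude of about the
    tide-adjusted zero, so the per-individual median floating-bout GPS
    altitude estimates a constant receiver bias; it is subtracted when the
    stage is enabled.  Individuals with fewer than ``min_bout_fixes``
    floating-bout fixes are left unchanged.
    """
    out = fixes.copy()
    out["gps_alt_corrected_m"] = out["gps_alt_m"].astype(float)
    if not enabled or bouts.empty:
        return out
    float_idx: dict[str, list] = {}
    for row in bouts.itertuples():
        float_idx.setdefault(str(row.individual_id), []).extend(row.fix_index)
    for ind, idx in float_idx.items():
        vals = out.loc[out.index.intersection(idx), "gps_alt_m"].dropna()
        if len(vals) < min_bout_fixes:
            continue
        bias = float(vals.median())
        mask = out["individual_id"].astype(str) == ind
        out.loc[mask, "gps_alt_corrected_m"] = out.loc[mask, "gps_alt_m"] - bias
    return out
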