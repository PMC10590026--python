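"""Readers and writers for the pipeline's file dialects.

All files are plain CSV (or YAML for configs) with an optional metadata
header of ``# key=value`` lines recording the config hash and seeds.
Timestamps are ISO-8601 UTC throughout; round-trips preserve numeric
values to better than 1e-9.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .environment import EnvironmentField
from .heights import HeightDistribution

FLOAT_FMT = "%.12g"


def _write_header(fh, meta: dict | None) -> None:
    for k, v in (meta or {}).items():
        fh.write(f"# {k}={v}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tracks(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    with open(path, "w") as fh:
        _write_header(fh, meta)
        out.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_tracks(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    bad = ts.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.values) + 2).tolist()
        raise ValueError(f"malformed timestamps at data rows {lines[:10]}")
    df["timestamp"] = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return df


def write_field_csv(field: EnvironmentField, path, meta: dict | None = None) -> None:
    """Gridded field as long CSV (time, lat, lon, msl, t2m)."""
    path = Path(path)
    long = field.grid.to_dataframe().reset_index()
    long["time"] = pd.DatetimeIndex(long["time"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    with open(path, "w") as fh:
        _write_header(fh, meta)
        long.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_field_csv(path, tide: pd.Series) -> EnvironmentField:
    df = pd.read_csv(path, comment="#")
    df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
    ds = df.set_index(["time", "lat", "lon"]).to_xarray()
    grid = xr.Dataset({"msl": ds["msl"], "t2m": ds["t2m"]})
    return EnvironmentField(grid=grid, tide=tide)


def write_tide_csv(tide: pd.Series, path, meta: dict | None = None, qc_flags=None) -> None:
    """BODC-like tide dialect: timestamp, height above Chart Datum, QC flag."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(tide.index).strftime("%Y-%m-%dT%H:%M:%SZ"),
            "height_m": tide.values,
            "qc_flag": np.zeros(len(tide), dtype=int) if qc_flags is None else qc_flags,
        }
    )
    with open(path, "w") as fh:
        _write_header(fh, meta)
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_tide_csv(path) -> tuple[pd.Series, int]:
    """Tide series with QC-flagged rows dropped; returns (series, n_dropped)."""
    df = pd.read_csv(path, comment="#")
    n0 = len(df)
    df = df[df["qc_flag"] == 0]
    ts = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    series = pd.Series(df["height_m"].values, index=pd.DatetimeIndex(ts), name="height_m")
    return series, n0 - len(df)


def write_distribution(dist: HeightDistribution, path, meta: dict | None = None) -> None:
    path = Path(path)
    header = dict(meta or {})
    header["n"] = dist.n
    for k, v in dist.group.items():
        header[f"group.{k}"] = v
    with open(path, "w") as fh:
        _write_header(fh, header)
        dist.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_distribution(path) -> HeightDistribution:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#")
    if abs(df["proportion"].sum() - 1.0) > 1e-6:
        raise ValueError(f"distribution proportions sum to {df['proportion'].sum():.4f}, not 1")
    group = {k[6:]: v for k, v in meta.items() if k.startswith("group.")}
    return HeightDistribution.from_frame(df, n=int(meta.get("n", 0)), group=group)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
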