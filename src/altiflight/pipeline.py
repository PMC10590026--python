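"""End-to-end orchestration: simulate -> clean -> classify -> calibrate ->
heights -> distributions -> collision risk -> comparisons.

The demo configuration emulates a two-colony, two-year tracking study; the
two years differ in synoptic pressure variability, mimicking
between-season weather differences.  Every stage seed derives from the
single pipeline seed, so a run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import altimetry, behaviour, crm, heights, io, preprocessing
from .synthetic import FLIGHT_STATES, SimConfig, simulate_deployment

COLONIES = {
    "isleofmay": (-2.556, 56.186),
    "havergate": (1.553, 52.084),
}


@dataclass
class PipelineConfig:
    out_dir: str | None = None
    seed: int = 0
    groups: list[dict] = dc_field(default_factory=list)  # colony/year/sim overrides
    staleness_limit_s: float = altimetry.DEFAULT_STALENESS_LIMIT_S
    calibration_min_bout_fixes: int = 3
    platform_radius_m: float = 10.0
    platforms: pd.DataFrame | None = None
    land_mask: object = None
    band_m: float = 1.0
    ceiling_m: float = 500.0
    smoothing_bandwidth_m: float = 2.0
    distribution_method: str = "kde"
    tolerance_fraction: float = 0.2
    em_max_iter: int = 200
    em_tol: float = 1e-6
    gps_bias_correction: bool = False
    per_state_crm: bool = False
    density_per_km2: float = 2.0
    n_farms: int = 12
    total_mw: float = 430.0

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = demo_groups()


def demo_groups(days: int = 10, n_individuals: int = 3) -> list[dict]:
    """Two colonies x two years; 2019 has the more unsettled pressure field."""
    groups = []
    for colony, (lon, lat) in COLONIES.items():
        for year, synoptic_sd in (("2019", 6.0), ("2020", 4.0)):
            dlon = 0.12 if colony == "havergate" else 0.15
            groups.append(
                {
                    "colony": colony,
                    "year": year,
                    "sim": {
                        "colony_lon": lon,
                        "colony_lat": lat,
                        "start": f"{year}-06-01T00:00:00Z",
                        "end": f"{year}-06-{days + 1:02d}T00:00:00Z",
                        "n_individuals": n_individuals,
                        "synoptic_sd_mbar": synoptic_sd,
                        "pressure_bias_mbar": 2.0,
                        "geofences": [
                            box(lon + dlon, lat - 0.08, lon + dlon + 0.25, lat + 0.08)
                        ],
                    },
                }
            )
    return groups


def _group_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))


def run_group(group: dict, config: PipelineConfig, seed: int) -> dict:
    """Simulate and process one colony-year deployment."""
    sim_cfg = SimConfig(**group.get("sim", {}))
    fixes, truth, env = simulate_deployment(sim_cfg, seed)
    counts = {"simulated": len(fixes)}

    fixes = fixes.join(truth[["state", "stratum"]].add_prefix("true_"))
    metrics = preprocessing.trajectory_metrics(fixes)
    rect = preprocessing.ColonyRectangle.around(
        sim_cfg.colony_lon, sim_cfg.colony_lat, sim_cfg.colony_halfwidth_km
    )
    trips = preprocessing.segment_trips(metrics, rect)
    counts["on_trip"] = len(trips)
    if config.land_mask is not None:
        trips = preprocessing.filter_offshore(trips, config.land_mask)
    counts["offshore"] = len(trips)
    trips = preprocessing.filter_platforms(trips, config.platforms, config.platform_radius_m)
    counts["after_platform_filter"] = len(trips)

    strata = preprocessing.split_by_rate(
        trips, sim_cfg.base_interval_s, sim_cfg.burst_interval_s, config.tolerance_fraction
    )

    labelled_parts = []
    excluded_individuals: list[str] = []
    for rate_name, stream in strata.items():
        stream = stream.dropna(subset=["speed_ms", "turn_rad"])
        keep_ids = []
        for ind, grp in stream.groupby("individual_id"):
            ok, _reason = preprocessing.bimodality_screen(grp["speed_ms"].values, seed=seed)
            (keep_ids if ok else excluded_individuals).append(str(ind))
        stream = stream[stream["individual_id"].astype(str).isin(keep_ids)]
        if len(stream) < 100:
            continue
        try:
            model = behaviour.fit_embc(
                stream["speed_ms"].values,
                np.abs(stream["turn_rad"].values),
                max_iter=config.em_max_iter,
                tol=config.em_tol,
                seed=seed,
            )
        except behaviour.DegenerateFitError:
            # a stratum without separable low/high structure (e.g. a sparse
            # burst stream) is dropped; the other stratum can still carry
            # the group
            counts[f"stratum_{rate_name}_unclassifiable"] = len(stream)
            continue
        cls = behaviour.classify_states(
            model, stream["speed_ms"].values, np.abs(stream["turn_rad"].values)
        )
        stream = stream.copy()
        stream["state"] = cls["state"].values
        stream["posterior"] = cls["posterior"].values
        stream["rate"] = "5-min" if rate_name == "base" else "10-s"
        labelled_parts.append(stream)
    if not labelled_parts:
        raise RuntimeError("no stratum had enough classifiable fixes")
    labelled = pd.concat(labelled_parts).sort_values(["individual_id", "timestamp"])
    counts["classified"] = len(labelled)

    bouts = behaviour.floating_bouts(
        labelled["state"].values,
        labelled["timestamp"].values,
        labelled["individual_id"].values,
        index=labelled.index.values,
    )
    counts["floating_bouts"] = len(bouts)
    records = altimetry.derive_calibration_offsets(
        bouts, labelled, env, min_fixes=config.calibration_min_bout_fixes
    )

    with_heights = altimetry.altimeter_heights(
        labelled, records, env, config.staleness_limit_s
    )
    with_heights = altimetry.heights_to_msl(with_heights, env)
    with_heights = altimetry.gps_bias_correction(
        with_heights, bouts, enabled=config.gps_bias_correction
    )
    counts["non_stale"] = int((~with_heights["stale"]).sum())

    with_heights["colony"] = group["colony"]
    with_heights["year"] = group["year"]
    with_heights["flight"] = with_heights["state"].isin(FLIGHT_STATES)
    return {
        "fixes": with_heights,
        "truth": truth,
        "env": env,
        "records": records,
        "bouts": bouts,
        "counts": counts,
        "sim_config": sim_cfg,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Full multi-group pipeline; returns the output bundle and writes CSVs
    plus a manifest when ``config.out_dir`` is set."""
    group_results = []
    manifest: dict = {"seed": config.seed, "groups": [], "stage_counts": {}}
    for i, group in enumerate(config.groups):
        gseed = _group_seed(config.seed, i)
        try:
            res = run_group(group, config, gseed)
        except Exception as err:  # surface the failing stage and context
            raise RuntimeError(
                f"pipeline failed in group {group.get('colony')}/{group.get('year')}: {err}"
            ) from err
        res["group"] = group
        group_results.append(res)
        manifest["groups"].append(
            {"colony": group["colony"], "year": group["year"], "seed": gseed, **res["counts"]}
        )

    # long-format comparison table: one row per fix x method, flight states only
    long_parts = []
    for res in group_results:
        df = res["fixes"]
        flight = df[df["flight"] & ~df["stale"]]
        gps_col = "gps_alt_corrected_m" if config.gps_bias_correction else "gps_alt_m"
        for method, col in (("GPS", gps_col), ("Altimeter", "height_msl_m")):
            part = flight[["individual_id", "timestamp", "colony", "year", "rate",
                           "state", "staleness_s"]].copy()
            part["method"] = method
            part["height_msl_m"] = flight[col].values
            long_parts.append(part)
    comparison = pd.concat(long_parts, ignore_index=True)

    summary = heights.summarize_heights(
        comparison, "height_msl_m", ["rate", "colony", "year", "method"]
    )

    distributions: dict[str, heights.HeightDistribution] = {}
    dist_keys = ["method", "rate"] + (["state"] if config.per_state_crm else [])
    for levels, grp in comparison.groupby(dist_keys):
        key = "_".join(str(v) for v in levels)
        if len(grp) < 100:
            continue
        distributions[key] = heights.estimate_height_distribution(
            grp["height_msl_m"].values,
            band_m=config.band_m,
            ceiling_m=config.ceiling_m,
            smoothing_bandwidth_m=config.smoothing_bandwidth_m,
            method=config.distribution_method,
            group=dict(zip(dist_keys, levels)),
        )

    glmm_results = {}
    for rate, block in comparison.groupby("rate"):
        if block["individual_id"].nunique() < 2:
            continue
        model = heights.fit_method_glmm(block)
        glmm_results[rate] = {
            "model": model,
            "contrasts": heights.pairwise_comparisons(model),
        }

    # staleness diagnostic on GPS/altimeter pairs
    paired = comparison.pivot_table(
        index=["individual_id", "timestamp"],
        columns="method",
        values="height_msl_m",
    ).dropna()
    stale_vals = comparison.groupby(["individual_id", "timestamp"])["staleness_s"].first()
    diag_df = pd.DataFrame(
        {
            "abs_diff_m": (paired["GPS"] - paired["Altimeter"]).abs(),
            "staleness_s": stale_vals.reindex(paired.index),
        }
    ).reset_index(drop=True)
    diagnostic = (
        heights.staleness_diagnostic(diag_df, seed=config.seed)
        if len(diag_df) >= 20
        else None
    )

    farms = crm.make_farm_configs(total_mw=config.total_mw, n_farms=config.n_farms)
    bird = crm.BirdParams()
    estimates = crm.run_crm(farms, bird, distributions, config.density_per_km2)
    comparisons_crm = {}
    for rate in comparison["rate"].unique():
        keys = [k for k in distributions if f"_{rate}" in k]
        sub = estimates[estimates["group"].isin(keys)]
        if sub["group"].nunique() >= 2:
            comparisons_crm[rate] = crm.compare_collisions(sub)

    bundle = {
        "comparison": comparison,
        "summary": summary,
        "distributions": distributions,
        "glmm": glmm_results,
        "staleness_diagnostic": diagnostic,
        "farms": farms,
        "collision_estimates": estimates,
        "collision_comparisons": comparisons_crm,
        "manifest": manifest,
        "groups": group_results,
    }
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    group_tags = [f"{g['group']['colony']}_{g['group']['year']}" for g in bundle["groups"]]
    meta = {
        "seed": config.seed,
        "config_hash": io.config_hash({"seed": config.seed, "groups": group_tags}),
    }

    def write_csv(df, path):
        with open(path, "w") as fh:
            io._write_header(fh, meta)
            df.to_csv(fh, index=False)

    for res, tag in zip(bundle["groups"], group_tags):
        io.write_tracks(
            res["fixes"].drop(columns=["flight"]), out / f"tracks_{tag}.csv", meta
        )
        io.write_tide_csv(res["env"].tide, out / f"tide_{tag}.csv", meta)
        write_csv(altimetry.records_frame(res["records"]), out / f"calibration_{tag}.csv")
    write_csv(bundle["summary"], out / "height_summary.csv")
    for key, dist in bundle["distributions"].items():
        io.write_distribution(dist, out / f"distribution_{key}.csv", meta)
    write_csv(bundle["collision_estimates"], out / "collision_estimates.csv")
    for rate, table in bundle["collision_comparisons"].items():
        write_csv(table, out / f"collision_tukey_{rate}.csv")
    manifest = dict(bundle["manifest"])
    if bundle["staleness_diagnostic"]:
        manifest["staleness_diagnostic"] = bundle["staleness_diagnostic"]
    io.write_yaml(manifest, out / "manifest.yaml")
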