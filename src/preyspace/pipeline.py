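"""End-to-end orchestration: simulate and/or analyze a study dataset.

``analyze`` runs the stages in dependency order — triangulate & filter
relocations, derive daily hunting pressure, build seasonal and
moving-window home ranges, fit the mixed-model suite, bootstrap the roost
PERMANOVAs, and summarize mortality — writing every result table
atomically and recording a run manifest (config hash, seeds, per-stage row
counts and wall times).  ``simulate`` first generates a synthetic dataset
from ground truth, then analyzes it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, io, risk, survival, telemetry, windows
from .permanova import subsample_bootstrap
from .config import RunConfig
from .homerange import seasonal_home_ranges, seasonal_shifts

logger = logging.getLogger(__name__)

RESULT_FILES = [
    "pressure.csv", "home_ranges.csv", "shifts.csv", "windows.csv",
    "window_steps.csv", "model_results.csv", "permanova_results.csv",
    "survival_curves.csv", "mortality_table.csv",
]

PERMANOVA_TERMS = ["risk", "sex", "risk:sex", "date_day"]


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate(config: RunConfig, data_dir, truth=None) -> dict:
    """Generate a synthetic dataset and write it under ``data_dir``."""
    from .synthetic import SimulationTruth, simulate_dataset
    if truth is None:
        truth = SimulationTruth(seed=config.seed)
    ds = simulate_dataset(truth)
    counts = io.write_dataset(ds, data_dir, config)
    logger.info("simulated dataset written to %s: %s", data_dir, counts)
    return counts


def _validate_inputs(config: RunConfig, data_dir: Path) -> None:
    required = [config.relocations_file, config.cameras_file,
                config.fates_file, config.sites_file]
    missing = [f for f in required if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input files in {data_dir}: {missing}")


def analyze(config: RunConfig, data_dir, out_dir) -> dict:
    """Run the full analysis on a dataset directory; returns the manifest."""
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    _validate_inputs(config, data_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {"config_hash": _config_hash(config), "seed": config.seed,
                "stages": {}}

    def _emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        io.write_table(df, path)
        written.append(path)

    def _stage(name: str, n_rows: int, t0: float) -> None:
        manifest["stages"][name] = {"rows": int(n_rows),
                                    "seconds": round(time.time() - t0, 3)}

    try:
        t0 = time.time()
        reloc = io.read_table(data_dir / config.relocations_file, "relocations")
        sites = io.read_sites(data_dir / config.sites_file)
        cameras = io.read_table(data_dir / config.cameras_file, "cameras")
        fates = io.read_table(data_dir / config.fates_file, "fates")
        veg_path = data_dir / config.vegetation_file
        veg = io.read_table(veg_path, "vegetation") if veg_path.exists() else pd.DataFrame()
        bear_path = data_dir / config.bearings_file
        bearings = (io.read_table(bear_path, "bearings")
                    if bear_path.exists() else pd.DataFrame())
        _stage("read", len(reloc), t0)

        # --- triangulation: rebuild fixes that carry bearing sets
        t0 = time.time()
        if len(bearings):
            tri = telemetry.triangulate_table(bearings,
                                              bearing_sd_deg=config.bearing_sd_deg)
            tri = tri[tri["converged"]]
            if "event_id" in reloc.columns:
                upd = tri.set_index("event_id")[["x", "y", "ellipse_area_m2"]]
                idx = reloc.set_index("event_id").index
                reloc = reloc.set_index("event_id")
                common = reloc.index.intersection(upd.index)
                reloc.loc[common, ["x", "y", "ellipse_area_m2"]] = upd.loc[common]
                reloc = reloc.reset_index()
                del idx
        _stage("triangulate", len(bearings), t0)

        # --- quality filter and season labels
        t0 = time.time()
        if "ellipse_area_m2" not in reloc.columns:
            reloc["ellipse_area_m2"] = 0.0
        reloc = telemetry.filter_relocations(
            reloc, daytime_max_m2=config.daytime_ellipse_max_m2,
            roost_max_m2=config.roost_ellipse_max_m2)
        reloc["season"] = reloc["date"].map(risk.classify_season)
        if "group" not in reloc.columns and "site" in reloc.columns:
            reloc = reloc.merge(sites[["site", "group"]], on="site", how="left")
        if "year" not in reloc.columns:
            reloc["year"] = pd.to_datetime(reloc["date"]).dt.year
        _stage("filter", len(reloc), t0)

        # --- hunting pressure
        t0 = time.time()
        pressure = risk.daily_pressure(cameras)
        pressure = pressure.merge(sites[["site", "group"]], on="site", how="left")
        if len(reloc):
            year = int(pd.to_datetime(reloc["date"]).dt.year.mode().iloc[0])
        else:
            year = int(pd.to_datetime(cameras["date"]).dt.year.mode().iloc[0])
        pressure_full = risk.extend_pressure_preseason(
            pressure, list(sites["site"]), year)
        pressure_full = pressure_full.merge(
            sites[["site", "group"]], on="site", how="left", suffixes=("", "_s"))
        if "group_s" in pressure_full.columns:
            pressure_full["group"] = pressure_full["group"].fillna(
                pressure_full["group_s"])
            pressure_full = pressure_full.drop(columns=["group_s"])
        _emit(pressure_full, "pressure.csv")
        _stage("pressure", len(pressure_full), t0)

        # --- seasonal home ranges and shifts
        t0 = time.time()
        seasonal = seasonal_home_ranges(reloc, min_fixes=config.min_fixes,
                                        n_cells=config.seasonal_grid_cells,
                                        center=config.hr_center)
        shifts = seasonal_shifts(seasonal) if len(seasonal) else pd.DataFrame()
        _emit(seasonal, "home_ranges.csv")
        _emit(shifts, "shifts.csv")
        _stage("seasonal", len(seasonal), t0)

        # --- moving-window home ranges
        t0 = time.time()
        win, steps = windows.moving_window_table(
            reloc, sites, pressure_full, half_width=config.window_half_width,
            n_cells=config.window_grid_cells, center=config.hr_center)
        _emit(win, "windows.csv")
        _emit(steps, "window_steps.csv")
        _stage("windows", len(win), t0)

        # --- mixed-model suite
        t0 = time.time()
        models = inference.space_use_model_suite(
            seasonal, shifts, win, steps, pressure=pressure,
            n_draws=config.n_draws, seed=config.seed,
            log_pressure_offset=config.log_pressure_offset)
        model_table = inference.results_to_frame(models)
        _emit(model_table, "model_results.csv")
        _stage("models", len(model_table), t0)

        # --- roost-vegetation PERMANOVA bootstraps
        t0 = time.time()
        perm_rows = []
        if len(veg):
            rng = np.random.default_rng(config.seed)
            for model_id in ("pre", "within", "nonuse"):
                try:
                    boot = subsample_bootstrap(
                        veg, model_id, n_iter=config.n_boot,
                        n_perm=config.n_perm, terms=PERMANOVA_TERMS,
                        metric=config.distance_metric,
                        seed=int(rng.integers(0, 2**31 - 1)))
                    tab = boot.summary()
                    tab.insert(0, "model", model_id)
                    perm_rows.append(tab)
                except ValueError as exc:
                    logger.warning("PERMANOVA model %s skipped: %s", model_id, exc)
        perm_table = (pd.concat(perm_rows, ignore_index=True)
                      if perm_rows else pd.DataFrame())
        _emit(perm_table, "permanova_results.csv")
        _stage("permanova", len(perm_table), t0)

        # --- survival
        t0 = time.time()
        opening = pd.Timestamp(f"{year}-{config.opening_day}")
        curves = survival.survival_curves(fates, opening)
        mort = survival.early_mortality_table(fates, opening)
        _emit(curves, "survival_curves.csv")
        _emit(mort, "mortality_table.csv")
        _stage("survival", len(curves), t0)

        manifest["row_counts"] = {k: v["rows"] for k, v in manifest["stages"].items()}
        manifest_path = out_dir / "manifest.json"
        tmp = manifest_path.with_suffix(".tmp")
        tmp.write_text(json.dumps(manifest, indent=1))
        os.replace(tmp, manifest_path)
        return manifest
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise


def run_pipeline(config: RunConfig, mode: str, data_dir, out_dir=None,
                 truth=None) -> dict:
    """Run the pipeline in "simulate" (generate + analyze) or "analyze" mode."""
    if mode not in ("simulate", "analyze"):
        raise ValueError("mode must be 'simulate' or 'analyze'")
    out_dir = Path(out_dir) if out_dir is not None else Path(data_dir) / "results"
    if mode == "simulate":
        simulate(config, data_dir, truth=truth)
    return analyze(config, data_dir, out_dir)
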