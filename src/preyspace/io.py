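"""Typed table readers/writers and GeoJSON site I/O.

CSVs are RFC-4180 with headers, ISO-8601 dates and '.' decimals; sites are
a GeoJSON FeatureCollection whose features carry ``site`` and ``group``
(risk) properties.  Writers are atomic (write to a temp file, then rename)
so a failed stage never leaves a partial output behind.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = {
    "relocations": ["individual", "sex", "date", "type", "x", "y"],
    "bearings": ["event_id", "individual", "timestamp", "station_x",
                 "station_y", "azimuth_deg"],
    "cameras": ["site", "date", "n_photos", "n_hunters"],
    "vegetation": ["plot_id", "plot_type", "individual", "site", "risk",
                   "sex", "date"],
    "fates": ["individual", "sex", "group"],
}

DATE_COLUMNS = {"date", "timestamp", "death_date", "censor_date",
                "first_date", "last_date", "median_date"}


def _validate(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    required = REQUIRED_COLUMNS.get(kind, [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if kind in REQUIRED_COLUMNS and extra:
        logger.debug("%s: extra columns %s carried through", path, extra)
    return df


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    """Read a CSV into a typed DataFrame (dates parsed, floats as floats)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    df = pd.read_csv(path)
    for col in df.columns:
        if col in DATE_COLUMNS:
            df[col] = pd.to_datetime(df[col], errors="coerce")
    if kind:
        _validate(df, kind, path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Atomic CSV write with ISO dates and full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            if (out[col].dropna().dt.time.astype(str) == "00:00:00").all():
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            else:
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(tmp, index=False, float_format="%.17g")
    os.replace(tmp, path)


def read_sites(path) -> pd.DataFrame:
    """GeoJSON FeatureCollection -> DataFrame(site, group, area_ha, polygon)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    fc = json.loads(path.read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        if "site" not in props or "group" not in props:
            raise ValueError(f"{path}: every feature needs 'site' and 'group' properties")
        poly = shape(feat["geometry"])
        rows.append({"site": props["site"], "group": props["group"],
                     "area_ha": props.get("area_ha", poly.area / 1e4),
                     "polygon": poly})
    return pd.DataFrame(rows)


def write_sites(sites: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    feats = []
    for _, row in sites.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": mapping(row["polygon"]),
            "properties": {"site": row["site"], "group": row["group"],
                           "area_ha": float(row["area_ha"])},
        })
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps({"type": "FeatureCollection", "features": feats},
                              indent=1))
    os.replace(tmp, path)


def write_truth(truth, path) -> None:
    tmp = Path(path).with_suffix(".tmp")
    tmp.write_text(yaml.safe_dump(truth.to_dict(), sort_keys=True))
    os.replace(tmp, path)


def read_truth(path):
    from .synthetic import SimulationTruth
    return SimulationTruth.from_dict(yaml.safe_load(Path(path).read_text()))


def write_dataset(ds, outdir, config=None) -> dict:
    """Write a SyntheticDataset as the pipeline's canonical input files."""
    from .config import RunConfig
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(ds.relocations, outdir / cfg.relocations_file)
    write_table(ds.bearing_sets, outdir / cfg.bearings_file)
    write_table(ds.camera_days, outdir / cfg.cameras_file)
    write_table(ds.vegetation, outdir / cfg.vegetation_file)
    write_table(ds.fates, outdir / cfg.fates_file)
    write_sites(ds.sites, outdir / cfg.sites_file)
    write_truth(ds.truth, outdir / cfg.truth_file)
    return {name: len(tab) for name, tab in (
        ("relocations", ds.relocations), ("bearings", ds.bearing_sets),
        ("cameras", ds.camera_days), ("vegetation", ds.vegetation),
        ("fates", ds.fates), ("sites", ds.sites))}


def write_ud_ascii(ud, path) -> None:
    """Export a UD grid as an ESRI ASCII raster (plain text)."""
    path = Path(path)
    lines = [
        f"ncols {ud.n_x}",
        f"nrows {ud.n_y}",
        f"xllcorner {ud.origin[0]:.6f}",
        f"yllcorner {ud.origin[1]:.6f}",
        f"cellsize {ud.cell_size:.6f}",
        "NODATA_value -9999",
    ]
    for row in ud.density[::-1]:  # ASCII rasters run north to south
        lines.append(" ".join(f"{v:.8e}" for v in row))
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text("\n".join(lines) + "\n")
    os.replace(tmp, path)
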