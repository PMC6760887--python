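"""Moving-window home ranges: a continuous-time view of space use.

Each window is the focal relocation plus its five predecessors and five
successors (11 fixes), so an individual with n time-ordered relocations
yields max(0, n - 10) windows, advanced one relocation at a time.  Every
window gets its own reference-bandwidth kernel UD, 95%/50% areas and core
center, the study site its 95% region overlaps most, and the mean hunting
pressure on that site over the window's date range; windows overlapping no
site fall back to the mean pressure across low-risk sites (a conservative
offsite estimate).  Displacements between successive core centers are
attributed to the *previous* window's pressure — the risk an individual was
moving away from.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .homerange import home_range_estimate
from .risk import season_day

logger = logging.getLogger(__name__)

HALF_WIDTH = 5  # relocations on each side of the focal fix
WINDOW_SIZE = 2 * HALF_WIDTH + 1


def build_windows(relocations: pd.DataFrame, half_width: int = HALF_WIDTH,
                  n_cells: int = 100, center: str = "centroid"):
    """Sliding-window home ranges for one individual.

    ``relocations`` must belong to a single individual with columns date, x,
    y (plus optional sex/site/group/year metadata carried through).  Rows
    are time-sorted; window t covers relocations t-5 .. t+5.  Columns of the
    result include the 95%/50% areas (ha), the 50% center, the median date
    and the window length in days (last minus first relocation date).

    Returns ``(windows, regions)``: the window table plus, per window, the
    (UDGrid, 95%-mask) pair used for site-overlap attribution.
    """
    if relocations["individual"].nunique() > 1:
        raise ValueError("build_windows takes relocations of one individual")
    df = relocations.sort_values("timestamp" if "timestamp" in relocations else "date",
                                 ignore_index=True)
    n = len(df)
    size = 2 * half_width + 1
    rows = []
    masks = []
    for t in range(half_width, n - half_width):
        grp = df.iloc[t - half_width: t + half_width + 1]
        est = home_range_estimate(grp[["x", "y"]].to_numpy(), n_cells=n_cells,
                                  center=center)
        dates = pd.to_datetime(grp["date"])
        rec = {
            "individual": df["individual"].iloc[0],
            "window": t - half_width,
            "first_date": dates.iloc[0],
            "last_date": dates.iloc[-1],
            "median_date": dates.iloc[half_width],
            "median_day": season_day(dates.iloc[half_width]),
            "window_length": int((dates.iloc[-1] - dates.iloc[0]).days),
            "n_fixes": size,
            "h": est["h"],
            "area95_ha": est["area95_ha"],
            "area50_ha": est["area50_ha"],
            "center_x": est["center50"][0],
            "center_y": est["center50"][1],
        }
        for col in ("sex", "group", "site", "year"):
            if col in df.columns:
                rec[f"home_{col}" if col == "site" else col] = df[col].iloc[0]
        rows.append(rec)
        masks.append((est["ud"], est["mask95"]))
    out = pd.DataFrame(rows)
    # regions returned out-of-band (attrs would be deep-copied on every
    # pandas indexing operation)
    return out, masks


def _overlap_area(ud, mask95, polygon) -> float:
    """Area (m^2) of 95%-region cells whose centers fall inside polygon."""
    yy, xx = np.nonzero(mask95)
    if len(xx) == 0:
        return 0.0
    xs = ud.x_centers[xx]
    ys = ud.y_centers[yy]
    minx, miny, maxx, maxy = polygon.bounds
    near = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
    if not near.any():
        return 0.0
    inside = int(shapely.contains_xy(polygon, xs[near], ys[near]).sum())
    return inside * ud.cell_area


class _PressureIndex:
    """Per-site daily pressure as day-number-indexed arrays (fast slicing)."""

    def __init__(self, pressure: pd.DataFrame, sites: pd.DataFrame):
        ptab = pressure.copy()
        ptab["date"] = pd.to_datetime(ptab["date"])
        self.t0 = ptab["date"].min()
        n_days = int((ptab["date"].max() - self.t0).days) + 1
        self.site_arr: dict[str, np.ndarray] = {}
        for s, g in ptab.groupby("site"):
            arr = np.full(n_days, np.nan)
            idx = (g["date"] - self.t0).dt.days.to_numpy()
            arr[idx] = g["pressure"].to_numpy(dtype=float)
            self.site_arr[s] = arr
        low = [s for s in sites.loc[sites["group"] == "low", "site"]
               if s in self.site_arr]
        self.low_mat = (np.vstack([self.site_arr[s] for s in low])
                        if low else np.empty((0, n_days)))
        self.n_days = n_days

    def _span(self, first, last) -> tuple[int, int]:
        i0 = int((pd.Timestamp(first) - self.t0).days)
        i1 = int((pd.Timestamp(last) - self.t0).days) + 1
        return max(i0, 0), min(max(i1, 0), self.n_days)

    def site_mean(self, site: str, first, last) -> float:
        arr = self.site_arr.get(site)
        if arr is None:
            return np.nan
        i0, i1 = self._span(first, last)
        chunk = arr[i0:i1]
        return float(np.nanmean(chunk)) if np.isfinite(chunk).any() else np.nan

    def low_mean(self, first, last) -> float:
        i0, i1 = self._span(first, last)
        chunk = self.low_mat[:, i0:i1]
        return float(np.nanmean(chunk)) if chunk.size and np.isfinite(chunk).any() else np.nan


def assign_site_and_pressure(windows: pd.DataFrame, sites: pd.DataFrame,
                             pressure: pd.DataFrame,
                             regions: list | None = None) -> pd.DataFrame:
    """Attach the overlapping study site and its mean pressure to windows.

    The assigned site is the one whose polygon overlaps the window's 95%
    region with the greatest area (ties broken by site id); the window's
    pressure is the mean of that site's daily values over [first_date,
    last_date], with missing days dropped.  Offsite windows (no overlap)
    receive the mean over low-risk sites for the same date range.  Windows
    whose date range has no pressure data at all carry NaN and are excluded
    from the models downstream.

    ``regions`` is the (UDGrid, mask95) list from :func:`build_windows`;
    without it the 50% center's containing site is used instead of the
    greatest-overlap rule.
    """
    pindex = _PressureIndex(pressure, sites)
    site_geoms = sorted(sites[["site", "polygon"]].itertuples(index=False),
                        key=lambda r: r[0])
    group_of = dict(zip(sites["site"], sites["group"]))

    assigned, press, grp_out = [], [], []
    win = windows.reset_index(drop=True)
    for i in range(len(win)):
        row = win.iloc[i]
        best_site, best_area = None, 0.0
        if regions is not None:
            ud, mask95 = regions[i]
            for s, poly in site_geoms:
                a = _overlap_area(ud, mask95, poly)
                if a > best_area:
                    best_site, best_area = s, a
        else:
            pt = Point(row["center_x"], row["center_y"])
            for s, poly in site_geoms:
                if poly.contains(pt):
                    best_site = s
                    break
        if best_site is not None:
            p = pindex.site_mean(best_site, row["first_date"], row["last_date"])
            assigned.append(best_site)
            grp_out.append(group_of.get(best_site))
        else:
            p = pindex.low_mean(row["first_date"], row["last_date"])
            assigned.append("offsite")
            grp_out.append("offsite")
        if np.isnan(p):
            logger.warning("window %s/%s: no pressure data in range, flagged",
                           row["individual"], row["window"])
        press.append(p)
    out = win.copy()
    out["assigned_site"] = assigned
    out["assigned_group"] = grp_out
    out["site"] = assigned  # random-effect grouping level used by the models
    out["pressure"] = press
    return out


def window_steps(windows: pd.DataFrame) -> pd.DataFrame:
    """Displacement between successive 50% centers of one individual.

    One step per adjacent window pair; ``previous_pressure`` is the earlier
    window's pressure (the risk being moved away from).
    """
    if len(windows) and windows["individual"].nunique() > 1:
        raise ValueError("window_steps takes windows of one individual")
    w = windows.sort_values("window", ignore_index=True)
    if len(w) < 2:
        return pd.DataFrame()
    a = w.iloc[:-1].reset_index(drop=True)
    b = w.iloc[1:].reset_index(drop=True)
    adjacent = (b["window"].to_numpy() - a["window"].to_numpy()) == 1
    out = pd.DataFrame({
        "individual": a["individual"],
        "from_window": a["window"].astype(int),
        "distance_m": np.hypot(b["center_x"].to_numpy() - a["center_x"].to_numpy(),
                               b["center_y"].to_numpy() - a["center_y"].to_numpy()),
        "previous_pressure": (a["pressure"] if "pressure" in w.columns
                              else np.nan),
        "median_day": a.get("median_day", np.nan),
        "median_date": a["median_date"],
        "window_length": a["window_length"],
    })
    for col in ("sex", "group", "site", "year"):
        if col in w.columns:
            out[col] = a[col]
    return out[adjacent].reset_index(drop=True)


def moving_window_table(relocations: pd.DataFrame, sites: pd.DataFrame,
                        pressure: pd.DataFrame, half_width: int = HALF_WIDTH,
                        n_cells: int = 100,
                        center: str = "centroid") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windows and steps for a whole population of relocations."""
    all_windows, all_steps = [], []
    for _ind, grp in relocations.groupby("individual", sort=True):
        if len(grp) < 2 * half_width + 1:
            continue
        w, regions = build_windows(grp, half_width=half_width, n_cells=n_cells,
                                   center=center)
        w = assign_site_and_pressure(w, sites, pressure, regions=regions)
        s = window_steps(w)
        all_windows.append(w)
        if len(s):
            all_steps.append(s)
    windows = (pd.concat(all_windows, ignore_index=True)
               if all_windows else pd.DataFrame())
    steps = pd.concat(all_steps, ignore_index=True) if all_steps else pd.DataFrame()
    return windows, steps
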