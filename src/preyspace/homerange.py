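"""Fixed-kernel utilization distributions and home-range isopleths.

A home range is summarized by the utilization distribution (UD): the
probability density of an animal's locations over a period, estimated here
with a bivariate Gaussian fixed-kernel density with the ad-hoc reference
bandwidth ``h_ref``.  Home ranges are volume isopleths of the UD: the 95%
isopleth is the conventional home range and the 50% isopleth the core area.

Coordinates are planar projected meters throughout; areas are reported in
hectares (m^2 / 1e4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 95% quantile of the chi-square distribution with 2 df; the squared
#: Mahalanobis radius enclosing 95% of a bivariate normal.
CHI2_2_95 = 5.991464547107979


def reference_bandwidth(points: np.ndarray) -> float:
    """Ad-hoc bivariate reference bandwidth ``h_ref``.

    h = 0.5 * (sd_x + sd_y) * n**(-1/6)

    with sample standard deviations (ddof=1).  This is the default smoothing
    parameter of the classical fixed-kernel home-range estimator.

    Parameters
    ----------
    points : (n, 2) array of x, y in meters.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, y) points")
    sd = pts.std(axis=0, ddof=1)
    if not np.all(np.isfinite(sd)) or np.all(sd == 0):
        raise ValueError("all points identical: bandwidth undefined")
    n = pts.shape[0]
    return 0.5 * (sd[0] + sd[1]) * n ** (-1.0 / 6.0)


@dataclass
class UDGrid:
    """Gridded utilization distribution.

    ``density`` holds the raw kernel density (1/m^2) on cell centers, shape
    (n_y, n_x) with row 0 at the grid origin (south-west corner).  With the
    required >= 3h padding the density integrates to 1 over the grid to well
    within 1%.
    """

    origin: tuple[float, float]
    cell_size: float
    n_x: int
    n_y: int
    density: np.ndarray
    h: float
    n_points: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.n_y, self.n_x):
            raise ValueError("density shape does not match grid dimensions")
        if self.h <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(self.density < 0):
            raise ValueError("negative density")

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.n_x) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.n_y) + 0.5) * self.cell_size

    def total_mass(self) -> float:
        """Probability mass captured by the grid (should be ~1)."""
        return float(self.density.sum() * self.cell_area)


def kernel_ud(
    points: np.ndarray,
    h: float | None = None,
    n_cells: int = 200,
    padding_factor: float = 3.0,
    grid: tuple[tuple[float, float], float, int, int] | None = None,
) -> UDGrid:
    """Bivariate Gaussian fixed-kernel UD on a regular grid.

    Density at a node z is ``(1/(n 2 pi h^2)) * sum_i exp(-|z - x_i|^2 / (2 h^2))``.

    Parameters
    ----------
    points : (n, 2) relocations in meters.
    h : bandwidth in meters; ``reference_bandwidth(points)`` when omitted.
    n_cells : cells along the longer grid axis when the grid is derived
        from the point bounding box (padded by ``padding_factor * h``).
    grid : explicit grid as (origin, cell_size, n_x, n_y); must cover all
        points with at least 3h padding or normalization would be broken.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    n = pts.shape[0]
    if h is None:
        h = reference_bandwidth(pts)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if grid is None:
        pad = padding_factor * h
        if padding_factor < 3.0:
            raise ValueError("padding_factor < 3 would truncate the kernels")
        span = (hi - lo) + 2 * pad
        cell = float(span.max()) / n_cells
        n_x = max(2, int(np.ceil(span[0] / cell)))
        n_y = max(2, int(np.ceil(span[1] / cell)))
        origin = (float(lo[0] - pad), float(lo[1] - pad))
    else:
        origin, cell, n_x, n_y = grid
        gx_hi = origin[0] + n_x * cell
        gy_hi = origin[1] + n_y * cell
        if (
            lo[0] - origin[0] < 3 * h
            or lo[1] - origin[1] < 3 * h
            or gx_hi - hi[0] < 3 * h
            or gy_hi - hi[1] < 3 * h
        ):
            raise ValueError("grid must cover the points with >= 3h padding")

    xc = origin[0] + (np.arange(n_x) + 0.5) * cell
    yc = origin[1] + (np.arange(n_y) + 0.5) * cell
    # separable Gaussian: outer product of per-axis kernels, summed over points
    kx = np.exp(-((xc[None, :] - pts[:, 0, None]) ** 2) / (2 * h * h))
    ky = np.exp(-((yc[None, :] - pts[:, 1, None]) ** 2) / (2 * h * h))
    dens = np.einsum("py,px->yx", ky, kx) / (n * 2 * np.pi * h * h)
    return UDGrid(origin=(float(origin[0]), float(origin[1])), cell_size=float(cell),
                  n_x=n_x, n_y=n_y, density=dens, h=float(h), n_points=n)


@dataclass
class IsoplethRegion:
    """Smallest set of grid cells holding probability mass >= p."""

    p: float
    area_ha: float
    mask: np.ndarray = field(repr=False)
    centroid: tuple[float, float]
    mode: tuple[float, float]


def isopleth(ud: UDGrid, p: float) -> IsoplethRegion:
    """Volume isopleth of a UD.

    Cells are ranked by density; the smallest prefix whose cumulative
    probability mass reaches ``p`` forms the region.  Raw (unrenormalized)
    mass is accumulated: the sliver of kernel mass truncated beyond the grid
    padding lies outside any interior isopleth, so renormalizing by the grid
    total would bias the region small.  If the grid holds less than ``p``
    total mass the region is every cell with nonzero density.  The region
    center is the density-weighted centroid of member cells; the density
    mode is also returned.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    dens = ud.density.ravel()
    order = np.argsort(dens)[::-1]
    mass = dens[order] * ud.cell_area
    total = mass.sum()
    if total <= 0:
        raise ValueError("UD carries no mass on the grid")
    cum = np.cumsum(mass)
    n_pos = int((mass > 0).sum())
    k = int(np.searchsorted(cum, p) + 1)
    k = min(k, n_pos)
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)

    area_ha = k * ud.cell_area / 1e4
    yy, xx = np.nonzero(mask)
    w = ud.density[yy, xx]
    xs = ud.x_centers[xx]
    ys = ud.y_centers[yy]
    centroid = (float(np.average(xs, weights=w)), float(np.average(ys, weights=w)))
    imode = int(np.argmax(dens))
    my, mx = np.unravel_index(imode, ud.density.shape)
    mode = (float(ud.x_centers[mx]), float(ud.y_centers[my]))
    return IsoplethRegion(p=p, area_ha=float(area_ha), mask=mask, centroid=centroid, mode=mode)


def home_range_estimate(points: np.ndarray, n_cells: int = 200,
                        center: str = "centroid") -> dict:
    """95%/50% home-range summary for one point set.

    Returns a dict with h, area95_ha, area50_ha, center50 (x, y) and the
    50%-region mask bundled with its grid (for site-overlap queries).
    """
    pts = np.asarray(points, dtype=float)
    h = reference_bandwidth(pts)
    ud = kernel_ud(pts, h=h, n_cells=n_cells)
    iso95 = isopleth(ud, 0.95)
    iso50 = isopleth(ud, 0.50)
    c50 = iso50.mode if center == "mode" else iso50.centroid
    return {
        "h": h,
        "ud": ud,
        "area95_ha": iso95.area_ha,
        "area50_ha": iso50.area_ha,
        "center50": c50,
        "mask95": iso95.mask,
        "mask50": iso50.mask,
        "n": pts.shape[0],
    }


def seasonal_home_ranges(
    relocations: pd.DataFrame,
    min_fixes: int = 10,
    n_cells: int = 200,
    center: str = "centroid",
) -> pd.DataFrame:
    """Per individual x season kernel home ranges.

    ``relocations`` needs columns individual, sex, season, x, y (season from
    :func:`preyspace.risk.classify_season`).  Individual-seasons with fewer
    than ``min_fixes`` relocations are omitted, matching the 10-location
    minimum conventional for kernel estimates at these sample sizes; each
    individual is eligible per season independently.
    """
    rows = []
    use = relocations[relocations["season"].isin(["pre", "early", "late"])]
    for (ind, season), grp in use.groupby(["individual", "season"], sort=True):
        if len(grp) < min_fixes:
            logger.debug("skipping %s/%s: %d < %d fixes", ind, season, len(grp), min_fixes)
            continue
        est = home_range_estimate(grp[["x", "y"]].to_numpy(), n_cells=n_cells, center=center)
        rec = {
            "individual": ind,
            "period": season,
            "n": est["n"],
            "h": est["h"],
            "area95_ha": est["area95_ha"],
            "area50_ha": est["area50_ha"],
            "center_x": est["center50"][0],
            "center_y": est["center50"][1],
        }
        for col in ("sex", "group", "site", "year"):
            if col in grp.columns:
                rec[col] = grp[col].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)


def seasonal_shifts(estimates: pd.DataFrame) -> pd.DataFrame:
    """Euclidean shift of the core-area (50%) center from the pre-season.

    One row per individual x contrast (pre_to_early, pre_to_late); an
    individual lacking either member of a pair contributes nothing, which is
    what makes the paired location analysis a smaller sample than the size
    analysis.
    """
    rows = []
    if len(estimates) == 0:
        return pd.DataFrame(rows)
    for ind, grp in estimates.groupby("individual", sort=True):
        by_period = grp.set_index("period")
        if "pre" not in by_period.index:
            continue
        pre = by_period.loc["pre"]
        for season, contrast in (("early", "pre_to_early"), ("late", "pre_to_late")):
            if season not in by_period.index:
                continue
            cur = by_period.loc[season]
            d = float(np.hypot(cur["center_x"] - pre["center_x"],
                               cur["center_y"] - pre["center_y"]))
            rec = {"individual": ind, "contrast": contrast, "distance_m": d}
            for col in ("sex", "group", "site", "year"):
                if col in grp.columns:
                    rec[col] = grp[col].iloc[0]
            rows.append(rec)
    return pd.DataFrame(rows)
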