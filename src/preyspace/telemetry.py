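"""Maximum-likelihood radio triangulation and relocation quality filtering.

A tagged animal is located by taking azimuth bearings from two or more known
stations within a short span (20 minutes by field protocol) and intersecting
them.  Bearing errors are modelled as von Mises on the circle; the location
estimate maximizes the resulting likelihood (the classical ML triangulation
estimator), with a covariance from the Fisher information and a 95%
confidence error ellipse whose area gates which fixes are usable.

Conventions: azimuths in degrees clockwise from grid north; coordinates in
projected meters (x east, y north).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homerange import CHI2_2_95

#: error-ellipse area thresholds (m^2) above which a fix is discarded
DAYTIME_ELLIPSE_MAX_M2 = 2000.0
ROOST_ELLIPSE_MAX_M2 = 1000.0

#: assumed bearing standard deviation (degrees) for the error ellipse
DEFAULT_BEARING_SD_DEG = 3.0

DAYTIME_TYPES = frozenset({"foraging", "loafing"})


@dataclass
class BearingSet:
    """One tracking event: simultaneous bearings on one animal."""

    individual: str
    timestamp: object
    stations: np.ndarray  # (k, 2) meters
    azimuths_deg: np.ndarray  # (k,) degrees clockwise from north
    intended_type: str = "loafing"

    def __post_init__(self) -> None:
        self.stations = np.atleast_2d(np.asarray(self.stations, dtype=float))
        self.azimuths_deg = np.atleast_1d(np.asarray(self.azimuths_deg, dtype=float))
        if self.stations.shape[0] != self.azimuths_deg.shape[0]:
            raise ValueError("one azimuth per station required")
        if self.stations.shape[0] < 2:
            raise ValueError("at least two bearings required")
        if np.any(self.azimuths_deg < 0) or np.any(self.azimuths_deg >= 360):
            raise ValueError("azimuths must lie in [0, 360)")


@dataclass
class TriangulationResult:
    estimate: tuple[float, float]
    covariance: np.ndarray
    ellipse_area_m2: float
    n_bearings: int
    converged: bool
    n_iter: int = 0


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles (radians) to (-pi, pi]."""
    return (angle + np.pi) % (2 * np.pi) - np.pi


def azimuth_to(point: np.ndarray, stations: np.ndarray) -> np.ndarray:
    """True azimuth (radians, clockwise from north) from each station to point."""
    d = np.asarray(point, dtype=float) - stations
    return np.arctan2(d[:, 0], d[:, 1])


def _ls_intersection(stations: np.ndarray, theta: np.ndarray) -> np.ndarray | None:
    """Least-squares intersection of the bearing lines (the starting value).

    Minimizes the sum of squared perpendicular distances to the bearing
    lines; returns None when all bearings are parallel (singular system).
    """
    # unit normal to a bearing with azimuth a is (cos a, -sin a)
    n = np.column_stack([np.cos(theta), -np.sin(theta)])
    A = np.einsum("ki,kj->ij", n, n)
    b = np.einsum("ki,kj,kj->i", n, n, stations)
    if np.linalg.matrix_rank(A, tol=1e-9 * max(np.trace(A), 1.0)) < 2:
        return None
    return np.linalg.solve(A, b)


def triangulate(
    bearings: BearingSet,
    bearing_sd_deg: float | None = DEFAULT_BEARING_SD_DEG,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> TriangulationResult:
    """ML location estimate for one bearing set.

    Maximizes the von Mises bearing likelihood ``sum_i cos(theta_i - mu_i(z))``
    by Fisher scoring from the least-squares line intersection.  The
    covariance is ``sigma^2 * (sum_i g_i g_i^T)^-1`` with ``g_i`` the gradient
    of the azimuth at the estimate and ``sigma`` the assumed bearing SD; the
    95% error ellipse area is ``pi * sqrt(det(cov)) * chi2_{2,0.95}``.

    ``bearing_sd_deg=None`` estimates sigma from the circular residuals
    (``sigma^2 = sum 2(1 - cos r) / (k - 2)``, needing k >= 3 bearings), so
    the ellipse then reflects the observed bearing scatter instead of an
    assumed receiver precision.

    Parallel bearings have no finite intersection and are flagged
    non-converged (NaN estimate) rather than raising.
    """
    st = bearings.stations
    theta = np.deg2rad(bearings.azimuths_deg)
    k = st.shape[0]

    z = _ls_intersection(st, theta)
    if z is None:
        return TriangulationResult(
            estimate=(np.nan, np.nan), covariance=np.full((2, 2), np.nan),
            ellipse_area_m2=np.nan, n_bearings=k, converged=False)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = z - st
        d2 = np.einsum("ij,ij->i", d, d)
        if np.any(d2 < 1e-12):
            raise ValueError("estimate coincides with a receiving station")
        mu = np.arctan2(d[:, 0], d[:, 1])
        r = _wrap(theta - mu)
        # gradient of mu wrt z: (dy, -dx) / d^2
        g = np.column_stack([d[:, 1], -d[:, 0]]) / d2[:, None]
        info = np.einsum("ki,kj->ij", g, g)
        score = g.T @ np.sin(r)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        z = z + step
        if np.linalg.norm(step) < tol:
            converged = True
            break

    d = z - st
    d2 = np.einsum("ij,ij->i", d, d)
    g = np.column_stack([d[:, 1], -d[:, 0]]) / d2[:, None]
    info = np.einsum("ki,kj->ij", g, g)
    if bearing_sd_deg is None:
        if k < 3:
            raise ValueError("residual-based bearing SD needs >= 3 bearings")
        r = _wrap(theta - np.arctan2(d[:, 0], d[:, 1]))
        sigma = np.sqrt(max(2.0 * np.sum(1.0 - np.cos(r)) / (k - 2), 1e-18))
    else:
        sigma = np.deg2rad(bearing_sd_deg)
    try:
        cov = sigma**2 * np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return TriangulationResult(
            estimate=(float(z[0]), float(z[1])), covariance=np.full((2, 2), np.nan),
            ellipse_area_m2=np.nan, n_bearings=k, converged=False, n_iter=it)
    cov = (cov + cov.T) / 2
    area = float(np.pi * np.sqrt(max(np.linalg.det(cov), 0.0)) * CHI2_2_95)
    return TriangulationResult(
        estimate=(float(z[0]), float(z[1])), covariance=cov,
        ellipse_area_m2=area, n_bearings=k, converged=converged, n_iter=it)


def bearing_log_likelihood(point, stations, azimuths_deg) -> float:
    """von Mises bearing log-likelihood (up to the concentration factor).

    Exposed so an exhaustive grid search can serve as an independent check
    of the scoring iteration.
    """
    theta = np.deg2rad(np.asarray(azimuths_deg, dtype=float))
    mu = azimuth_to(np.asarray(point, dtype=float), np.atleast_2d(stations))
    return float(np.cos(theta - mu).sum())


def filter_relocations(
    fixes: pd.DataFrame,
    daytime_max_m2: float = DAYTIME_ELLIPSE_MAX_M2,
    roost_max_m2: float = ROOST_ELLIPSE_MAX_M2,
) -> pd.DataFrame:
    """Discard triangulated fixes with oversized error ellipses.

    Daytime fixes (foraging, loafing) are kept when the 95% error-ellipse
    area is at most 2000 m^2 (a ~25 m radius); roosting fixes need at most
    1000 m^2 because roosts are revisited on the ground for vegetation
    sampling.  Direct (visual) fixes always pass.  Order is preserved and
    the operation is idempotent.
    """
    if len(fixes) == 0:
        return fixes.copy()
    area = fixes["ellipse_area_m2"].to_numpy(dtype=float)
    loc_type = fixes["type"].astype(str)
    direct = fixes.get("source", pd.Series("triangulated", index=fixes.index)).eq("direct")
    limit = np.where(loc_type.isin(DAYTIME_TYPES), daytime_max_m2, roost_max_m2)
    keep = direct.to_numpy() | (area <= limit)
    return fixes.loc[keep].copy()


def triangulate_table(
    bearing_table: pd.DataFrame,
    bearing_sd_deg: float = DEFAULT_BEARING_SD_DEG,
) -> pd.DataFrame:
    """Triangulate a long-format bearings table.

    ``bearing_table`` has one row per bearing with columns event_id,
    individual, timestamp, type, station_x, station_y, azimuth_deg.  Returns
    one row per event with the ML estimate, ellipse area and convergence
    flag; non-converged events carry NaN coordinates.
    """
    out = []
    for event, grp in bearing_table.groupby("event_id", sort=True):
        bs = BearingSet(
            individual=grp["individual"].iloc[0],
            timestamp=grp["timestamp"].iloc[0],
            stations=grp[["station_x", "station_y"]].to_numpy(),
            azimuths_deg=grp["azimuth_deg"].to_numpy(),
            intended_type=grp["type"].iloc[0] if "type" in grp else "loafing",
        )
        res = triangulate(bs, bearing_sd_deg=bearing_sd_deg)
        out.append({
            "event_id": event,
            "individual": bs.individual,
            "timestamp": bs.timestamp,
            "type": bs.intended_type,
            "x": res.estimate[0],
            "y": res.estimate[1],
            "ellipse_area_m2": res.ellipse_area_m2,
            "n_bearings": res.n_bearings,
            "converged": res.converged,
        })
    return pd.DataFrame(out)
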