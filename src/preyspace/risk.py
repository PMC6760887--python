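"""Hunting-pressure (predation-risk) metric and season calendar.

Predation risk is proxied by hunting pressure: the mean number of hunters
per camera photo, per site, per day.  The study calendar splits into a
pre-hunting season (1-25 October), an early hunting season (27 October -
23 November, when pressure peaks) and a late season (24 November - 15
December); 26 October (opening eve) belongs to none of the defined windows
and is excluded.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

SEASON_PRE = "pre"
SEASON_EARLY = "early"
SEASON_LATE = "late"
EXCLUDED = "excluded"

# (start month, start day, end month, end day), inclusive, within one year
SEASON_WINDOWS = {
    SEASON_PRE: ((10, 1), (10, 25)),
    SEASON_EARLY: ((10, 27), (11, 23)),
    SEASON_LATE: ((11, 24), (12, 15)),
}

#: first day of the hunting season (month, day)
OPENING_DAY = (10, 27)
STUDY_START = (10, 1)
STUDY_END = (12, 15)


def classify_season(date) -> str:
    """Season label for a calendar date (year-agnostic month/day windows)."""
    date = pd.Timestamp(date)
    md = (date.month, date.day)
    for label, (start, end) in SEASON_WINDOWS.items():
        if start <= md <= end:
            return label
    return EXCLUDED


def season_day(date, year: int | None = None) -> int:
    """Day-of-study index: 0 on 1 October of the date's (or given) year."""
    date = pd.Timestamp(date)
    y = year if year is not None else date.year
    return (date - pd.Timestamp(dt.date(y, *STUDY_START))).days


def opening_date(year: int) -> pd.Timestamp:
    return pd.Timestamp(dt.date(year, *OPENING_DAY))


def daily_pressure(camera_days: pd.DataFrame) -> pd.DataFrame:
    """Mean hunters per photo, per site, per day.

    Rows from multiple cameras on the same site-day are pooled by summing
    hunters and photos before taking the ratio (ratio of sums: every photo
    weighs equally; a mean of per-camera ratios would not).  Site-days with
    zero photos (camera failure) yield a missing pressure, not zero.

    Returns columns site, date, n_photos, n_hunters, pressure, season.
    """
    req = {"site", "date", "n_photos", "n_hunters"}
    missing = req - set(camera_days.columns)
    if missing:
        raise ValueError(f"camera table missing columns: {sorted(missing)}")
    df = camera_days.copy()
    df["date"] = pd.to_datetime(df["date"])
    agg = (
        df.groupby(["site", "date"], as_index=False)[["n_photos", "n_hunters"]]
        .sum()
        .sort_values(["site", "date"], ignore_index=True)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["pressure"] = agg["n_hunters"].to_numpy(float) / agg["n_photos"].to_numpy(float)
    agg.loc[agg["n_photos"] == 0, "pressure"] = np.nan
    agg["season"] = agg["date"].map(classify_season)
    return agg


def extend_pressure_preseason(pressure: pd.DataFrame, sites: list[str],
                              year: int) -> pd.DataFrame:
    """Prepend zero-pressure rows for pre-season dates (no legal hunting).

    Cameras run only during the hunting season, but moving-window home
    ranges begin before it; pressure before the opening date is zero by
    regulation, so the pipeline materializes those rows explicitly.
    """
    start = pd.Timestamp(dt.date(year, *STUDY_START))
    end = opening_date(year) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D")
    pre = pd.DataFrame(
        [{"site": s, "date": d, "n_photos": 0, "n_hunters": 0,
          "pressure": 0.0, "season": classify_season(d)}
         for s in sites for d in dates]
    )
    out = pd.concat([pre, pressure], ignore_index=True)
    return out.sort_values(["site", "date"], ignore_index=True)


def fit_risk_model(pressure: pd.DataFrame, n_draws: int = 5000,
                   seed: int | None = None):
    """Mixed model of hunting pressure on risk group x season.

    Gaussian LMM: pressure ~ group * season (early/late only) with a study
    site random intercept; reference cell high-risk/early so coefficients
    read as departures from the riskiest period.  Inference by posterior
    simulation (see :mod:`preyspace.inference`).
    """
    from .inference import MixedPosteriorModel, ModelSpec

    data = pressure[pressure["season"].isin([SEASON_EARLY, SEASON_LATE])].copy()
    data = data.dropna(subset=["pressure"])
    if "group" not in data.columns:
        raise ValueError("pressure table needs a risk-group column")
    if data["site"].nunique() < 2:
        raise ValueError("site random intercept needs at least two sites")
    spec = ModelSpec(
        response="pressure",
        transform="identity",
        fixed="C(group, Treatment('high')) * C(season, Treatment('early'))",
        random=["site"],
    )
    res = MixedPosteriorModel(data, spec).fit()
    res.simulate_posterior(n_draws=n_draws, seed=seed)
    return res
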