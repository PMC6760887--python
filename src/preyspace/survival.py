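"""Fate tracking: surviving-proportion curves and early-season mortality.

The surviving proportion of a sex x risk-group cohort on day ``d`` of the
hunting season is the product-limit (Kaplan-Meier) estimate at that day:
individuals lost to collar failure are right-censored (removed from both
numerator and denominator from their censor day) rather than counted as
deaths.  With no censoring the estimate reduces exactly to the naive
alive-count ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _day_index(dates, opening) -> np.ndarray:
    """1-based day of season: the opening date itself is day 1."""
    delta = pd.to_datetime(dates) - pd.Timestamp(opening)
    return np.asarray(delta.dt.days if hasattr(delta, "dt") else delta.days) + 1


def _cohort(fates: pd.DataFrame, opening) -> pd.DataFrame:
    """Individuals alive at the season onset, with event/censor day indices."""
    f = fates.copy()
    f["death_date"] = pd.to_datetime(f.get("death_date"), errors="coerce")
    f["censor_date"] = pd.to_datetime(f.get("censor_date"), errors="coerce")
    opening = pd.Timestamp(opening)
    dead_before = f["death_date"].notna() & (f["death_date"] < opening)
    censored_before = f["censor_date"].notna() & (f["censor_date"] < opening)
    f = f[~dead_before & ~censored_before].copy()
    f["event_day"] = np.where(f["death_date"].notna(),
                              _day_index(f["death_date"], opening), np.nan)
    f["censor_day"] = np.where(f["censor_date"].notna(),
                               _day_index(f["censor_date"], opening), np.nan)
    return f


def surviving_proportion(fates: pd.DataFrame, opening, day: int,
                         censoring: str = "km") -> float:
    """Product-limit surviving proportion of a cohort at season day ``day``.

    ``fates`` holds one row per individual (already restricted to the group
    of interest) with death_date / censor_date columns.  ``censoring``:
    "km" right-censors collar losses (product-limit); "drop" removes
    censored individuals from the cohort entirely.
    """
    if day < 0:
        raise ValueError("day must be >= 0 (0 = season onset)")
    cohort = _cohort(fates, opening)
    if censoring == "drop":
        cohort = cohort[cohort["censor_day"].isna()]
    elif censoring != "km":
        raise ValueError("censoring must be 'km' or 'drop'")
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort at season onset")
    if day == 0:
        return 1.0
    event_days = cohort["event_day"].dropna().astype(int)
    censor_days = cohort["censor_day"].dropna().astype(int)
    s = 1.0
    for t in range(1, day + 1):
        at_risk = n - int((event_days < t).sum()) - int((censor_days < t).sum())
        deaths = int((event_days == t).sum())
        if at_risk > 0 and deaths > 0:
            s *= 1.0 - deaths / at_risk
    return float(s)


def survival_curves(fates: pd.DataFrame, opening, n_days: int = 50,
                    by: tuple[str, ...] = ("sex", "group"),
                    censoring: str = "km") -> pd.DataFrame:
    """Daily surviving-proportion curves per sex x risk group.

    Returns long-format rows (group columns, day, proportion) suitable for
    a survival figure; day 0 is the season onset with proportion 1.
    """
    rows = []
    for keys, grp in fates.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        cohort = _cohort(grp, opening)
        if censoring == "drop":
            cohort = cohort[cohort["censor_day"].isna()]
        n = len(cohort)
        if n == 0:
            continue
        event_days = cohort["event_day"].dropna().astype(int).to_numpy()
        censor_days = cohort["censor_day"].dropna().astype(int).to_numpy()
        s = 1.0
        for day in range(0, n_days + 1):
            if day > 0:
                at_risk = n - int((event_days < day).sum()) - int((censor_days < day).sum())
                deaths = int((event_days == day).sum())
                if at_risk > 0 and deaths > 0:
                    s *= 1.0 - deaths / at_risk
            rec = dict(zip(by, keys))
            rec["day"] = day
            rec["proportion"] = s
            rows.append(rec)
    return pd.DataFrame(rows)


def early_mortality_table(fates: pd.DataFrame, opening, day: int = 10,
                          by: tuple[str, ...] = ("sex", "group"),
                          censoring: str = "km") -> pd.DataFrame:
    """Percent mortality over the first ``day`` days per sex x risk group.

    100 * (1 - surviving_proportion(day)); with harvest restricted to males,
    the high-risk male cell dominates this table.
    """
    rows = []
    for keys, grp in fates.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rec = dict(zip(by, keys))
        rec["n_onset"] = len(_cohort(grp, opening))
        try:
            rec["pct_mortality"] = 100.0 * (
                1.0 - surviving_proportion(grp, opening, day, censoring=censoring))
        except ValueError:
            rec["pct_mortality"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
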