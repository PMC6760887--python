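"""Moving-window construction, site/pressure attribution, and steps."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from preyspace.windows import (assign_site_and_pressure, build_windows,
                               moving_window_table, window_steps)


def _reloc(n, rng, start="2013-10-05", individual="P1", center=(0.0, 0.0)):
    dates = pd.date_range(start, periods=n, freq="2D")
    xy = rng.normal(0, 150, (n, 2)) + np.asarray(center)
    return pd.DataFrame({
        "individual": individual, "sex": "F", "date": dates,
        "timestamp": dates, "x": xy[:, 0], "y": xy[:, 1],
        "site": "S1", "group": "high", "year": 2013,
    })


def _sites():
    return pd.DataFrame([
        {"site": "S1", "group": "high", "area_ha": 100.0,
         "polygon": Polygon([(-500, -500), (500, -500), (500, 500), (-500, 500)])},
        {"site": "S2", "group": "low", "area_ha": 100.0,
         "polygon": Polygon([(9500, -500), (10500, -500), (10500, 500), (9500, 500)])},
    ])


def _pressure(values_by_site, dates):
    rows = []
    for site, val in values_by_site.items():
        for d in dates:
            rows.append({"site": site, "date": d, "pressure": val})
    return pd.DataFrame(rows)


class TestBuildWindows:
    @pytest.mark.parametrize("n,expected", [(10, 0), (11, 1), (25, 15), (5, 0)])
    def test_window_count_is_n_minus_ten(self, rng, n, expected):
        w, regions = build_windows(_reloc(n, rng), n_cells=50)
        assert len(w) == expected
        assert len(regions) == expected

    def test_eleven_members_and_length(self, rng):
        w, _ = build_windows(_reloc(13, rng), n_cells=50)
        assert (w["n_fixes"] == 11).all()
        assert (w["window_length"] == 20).all()  # 11 fixes every 2 days
        assert (w["area95_ha"] >= w["area50_ha"]).all()

    def test_multiple_individuals_rejected(self, rng):
        df = pd.concat([_reloc(12, rng), _reloc(12, rng, individual="P2")])
        with pytest.raises(ValueError):
            build_windows(df)


class TestAttribution:
    def test_window_inside_site_gets_site_mean(self, rng):
        reloc = _reloc(11, rng)
        w, regions = build_windows(reloc, n_cells=50)
        dates = pd.date_range("2013-10-01", "2013-12-15")
        out = assign_site_and_pressure(w, _sites(),
                                       _pressure({"S1": 0.5, "S2": 0.1}, dates),
                                       regions=regions)
        assert out["assigned_site"].iloc[0] == "S1"
        assert out["pressure"].iloc[0] == pytest.approx(0.5)

    def test_offsite_window_falls_back_to_low_risk_mean(self, rng):
        reloc = _reloc(11, rng, center=(50000.0, 50000.0))
        w, regions = build_windows(reloc, n_cells=50)
        dates = pd.date_range("2013-10-01", "2013-12-15")
        out = assign_site_and_pressure(w, _sites(),
                                       _pressure({"S1": 0.5, "S2": 0.1}, dates),
                                       regions=regions)
        assert out["assigned_site"].iloc[0] == "offsite"
        assert out["pressure"].iloc[0] == pytest.approx(0.1)

    def test_constant_pressure_independent_of_geometry(self, rng):
        reloc = _reloc(15, rng)
        w, regions = build_windows(reloc, n_cells=50)
        dates = pd.date_range("2013-10-01", "2013-12-15")
        out = assign_site_and_pressure(w, _sites(),
                                       _pressure({"S1": 0.2, "S2": 0.2}, dates),
                                       regions=regions)
        assert np.allclose(out["pressure"], 0.2)

    def test_pressure_respects_date_range_exactly(self, rng):
        reloc = _reloc(11, rng)
        w, regions = build_windows(reloc, n_cells=50)
        first, last = w["first_date"].iloc[0], w["last_date"].iloc[0]
        dates = pd.date_range("2013-10-01", "2013-12-15")
        base = _pressure({"S1": 0.3, "S2": 0.0}, dates)
        edited = base.copy()
        outside = (edited["date"] < first) | (edited["date"] > last)
        edited.loc[outside & (edited["site"] == "S1"), "pressure"] = 99.0
        p0 = assign_site_and_pressure(w, _sites(), base, regions=regions)
        p1 = assign_site_and_pressure(w, _sites(), edited, regions=regions)
        assert p0["pressure"].iloc[0] == p1["pressure"].iloc[0]

    def test_missing_pressure_dates_dropped_not_imputed(self, rng):
        reloc = _reloc(11, rng)
        w, regions = build_windows(reloc, n_cells=50)
        first = w["first_date"].iloc[0]
        dates = pd.date_range(first, periods=3)  # only 3 of ~21 days present
        out = assign_site_and_pressure(w, _sites(),
                                       _pressure({"S1": 0.4}, dates),
                                       regions=regions)
        assert out["pressure"].iloc[0] == pytest.approx(0.4)

    def test_no_pressure_data_flags_nan(self, rng):
        reloc = _reloc(11, rng)
        w, regions = build_windows(reloc, n_cells=50)
        far = pd.date_range("2014-06-01", periods=5)
        out = assign_site_and_pressure(w, _sites(), _pressure({"S1": 0.4}, far),
                                       regions=regions)
        assert np.isnan(out["pressure"].iloc[0])


class TestSteps:
    def test_k_windows_give_k_minus_one_steps(self, rng):
        w, regions = build_windows(_reloc(16, rng), n_cells=50)
        w["pressure"] = np.arange(len(w), dtype=float)
        steps = window_steps(w)
        assert len(steps) == len(w) - 1
        # pressure attributed from the *previous* window
        assert np.allclose(steps["previous_pressure"], np.arange(len(w) - 1))

    def test_near_identical_windows_small_distance(self, rng):
        # 12 nearly coincident fixes: exchanging one fix barely moves the center
        reloc = _reloc(12, rng)
        reloc[["x", "y"]] = rng.normal(0, 1.0, (12, 2))
        w, _ = build_windows(reloc, n_cells=50)
        w["pressure"] = 0.0
        steps = window_steps(w)
        assert (steps["distance_m"] < 10).all()

    def test_center_jump_localized(self, rng):
        reloc = _reloc(30, rng)
        reloc.loc[15:, ["x", "y"]] += 5000.0
        w, _ = build_windows(reloc, n_cells=60)
        w["pressure"] = 0.0
        steps = window_steps(w)
        peak = steps["distance_m"].idxmax()
        assert 5 <= steps.loc[peak, "from_window"] <= 15


def test_population_window_total(rng, small_dataset):
    reloc = small_dataset.relocations
    dates = pd.date_range("2013-10-01", "2013-12-15")
    pressure = pd.concat([
        pd.DataFrame({"site": s, "date": dates, "pressure": 0.1})
        for s in small_dataset.sites["site"]], ignore_index=True)
    sub = reloc[reloc["individual"].isin(reloc["individual"].unique()[:6])]
    windows, steps = moving_window_table(sub, small_dataset.sites, pressure,
                                         n_cells=40)
    expected = sum(max(0, n - 10) for n in sub.groupby("individual").size())
    assert len(windows) == expected
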