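"""Triangulation geometry, the grid-search oracle, and quality filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preyspace.synthetic import simulate_bearing_set
from preyspace.telemetry import (BearingSet, bearing_log_likelihood,
                                 filter_relocations, triangulate,
                                 triangulate_table)


def _true_azimuths(point, stations):
    d = np.asarray(point, float) - np.asarray(stations, float)
    return np.rad2deg(np.arctan2(d[:, 0], d[:, 1])) % 360.0


class TestTriangulate:
    def test_noiseless_three_bearings_recover_target(self):
        st3 = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        az = _true_azimuths((500.0, 500.0), st3)
        res = triangulate(BearingSet("b1", None, st3, az))
        assert res.converged
        assert res.estimate == pytest.approx((500.0, 500.0), abs=1e-6)

    def test_ellipse_area_shrinks_with_assumed_bearing_sd(self):
        st3 = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        az = _true_azimuths((500.0, 500.0), st3)
        areas = [triangulate(BearingSet("b", None, st3, az), bearing_sd_deg=s).ellipse_area_m2
                 for s in (3.0, 1.0, 0.1, 0.01)]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        assert areas[-1] < 1e-2 * areas[0]

    def test_two_perpendicular_bearings_intersect_exactly(self):
        stations = np.array([[0.0, 300.0], [400.0, 0.0]])
        az = _true_azimuths((400.0, 300.0), stations)
        res = triangulate(BearingSet("b2", None, stations, az))
        assert res.estimate == pytest.approx((400.0, 300.0), abs=1e-6)

    def test_parallel_bearings_flagged_nonconverged(self):
        stations = np.array([[0.0, 0.0], [100.0, 0.0]])
        res = triangulate(BearingSet("b3", None, stations, [0.0, 0.0]))
        assert not res.converged
        assert np.isnan(res.estimate[0])

    def test_fewer_than_two_bearings_rejected(self):
        with pytest.raises(ValueError):
            BearingSet("b4", None, np.array([[0.0, 0.0]]), [45.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_ml_matches_likelihood_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        target = rng.uniform(300, 700, 2)
        angles = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, 4, endpoint=False)
        stations = target + 400 * np.column_stack([np.cos(angles), np.sin(angles)])
        bs = simulate_bearing_set(target, stations, kappa=200.0, seed=rng)
        res = triangulate(BearingSet("o", None, bs["stations"], bs["azimuths_deg"]))
        grid = np.arange(-30, 31, 1.0)
        ll = np.array([[bearing_log_likelihood(res.estimate + np.array([dx, dy]),
                                               bs["stations"], bs["azimuths_deg"])
                        for dx in grid] for dy in grid])
        iy, ix = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(grid[ix]) <= 1.0 and abs(grid[iy]) <= 1.0

    def test_ellipse_area_decreases_with_bearing_concentration(self):
        # residual-estimated SD: wider von Mises noise -> larger ellipses
        rng = np.random.default_rng(7)
        target = np.array([500.0, 500.0])
        stations = np.array([[0, 0], [1000, 0], [0, 1000], [1000, 1000]], float)
        means = []
        for kappa in (50.0, 800.0):
            areas = []
            for _ in range(200):
                bs = simulate_bearing_set(target, stations, kappa, seed=rng)
                r = triangulate(BearingSet("m", None, bs["stations"],
                                           bs["azimuths_deg"]), bearing_sd_deg=None)
                if r.converged:
                    areas.append(r.ellipse_area_m2)
            means.append(np.mean(areas))
        assert means[0] > means[1]

    def test_ellipse_area_decreases_with_more_bearings(self):
        rng = np.random.default_rng(8)
        target = np.array([0.0, 0.0])
        means = []
        for k in (3, 8):
            angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
            stations = 400 * np.column_stack([np.cos(angles), np.sin(angles)])
            areas = []
            for _ in range(200):
                bs = simulate_bearing_set(target, stations, 300.0, seed=rng)
                r = triangulate(BearingSet("m", None, bs["stations"],
                                           bs["azimuths_deg"]))
                if r.converged:
                    areas.append(r.ellipse_area_m2)
            means.append(np.mean(areas))
        assert means[0] > means[1]


def _fix_frame(rows):
    return pd.DataFrame(rows, columns=["individual", "type", "ellipse_area_m2",
                                       "source"])


class TestFilter:
    @pytest.mark.parametrize("loc_type,area,kept", [
        ("loafing", 2500.0, False),   # above the daytime gate
        ("loafing", 1500.0, True),
        ("foraging", 2000.0, True),   # at the gate
        ("roosting", 1500.0, False),  # roosts held to the stricter gate
        ("roosting", 900.0, True),
    ])
    def test_thresholds(self, loc_type, area, kept):
        df = _fix_frame([{"individual": "a", "type": loc_type,
                          "ellipse_area_m2": area, "source": "triangulated"}])
        assert (len(filter_relocations(df)) == 1) is kept

    def test_direct_fixes_always_kept(self):
        df = _fix_frame([{"individual": "a", "type": "loafing",
                          "ellipse_area_m2": 1e6, "source": "direct"}])
        assert len(filter_relocations(df)) == 1

    def test_zero_ellipse_all_retained_and_empty_ok(self):
        df = _fix_frame([{"individual": "a", "type": t, "ellipse_area_m2": 0.0,
                          "source": "triangulated"}
                         for t in ("foraging", "loafing", "roosting")])
        assert len(filter_relocations(df)) == 3
        assert len(filter_relocations(df.iloc[:0])) == 0

    @given(st.lists(st.tuples(
        st.sampled_from(["foraging", "loafing", "roosting"]),
        st.floats(0, 5000, allow_nan=False)), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_order_preserving(self, fixes):
        df = _fix_frame([{"individual": "a", "type": t, "ellipse_area_m2": a,
                          "source": "triangulated"} for t, a in fixes])
        once = filter_relocations(df)
        assert once.equals(filter_relocations(once))
        assert list(once.index) == sorted(once.index)


def test_triangulate_table_roundtrip(rng):
    rows = []
    for e in range(3):
        target = rng.uniform(0, 1000, 2)
        stations = target + rng.normal(0, 400, (3, 2))
        az = _true_azimuths(target, stations)
        for i in range(3):
            rows.append({"event_id": f"E{e}", "individual": "p", "timestamp": e,
                         "type": "loafing", "station_x": stations[i, 0],
                         "station_y": stations[i, 1], "azimuth_deg": az[i]})
    out = triangulate_table(pd.DataFrame(rows))
    assert len(out) == 3
    assert out["converged"].all()
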