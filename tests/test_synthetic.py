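"""Ground-truth generator: determinism, invariants, and effect wiring."""

import numpy as np
import pandas as pd
import pytest

from preyspace.risk import classify_season
from preyspace.synthetic import (SimulationTruth, simulate_bearing_set,
                                 simulate_dataset)

TINY = {"F": {"high": 2, "low": 2}, "M": {"high": 2, "low": 2}}


class TestValidation:
    def test_zero_individuals_rejected(self):
        truth = SimulationTruth(n_individuals={"F": {"high": 0}})
        with pytest.raises(ValueError, match="individual"):
            simulate_dataset(truth)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth(natural_hazard=-0.1).validate()

    def test_inflation_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth(range_inflation=0.5).validate()

    def test_truth_roundtrip(self):
        t = SimulationTruth(seed=3, n_individuals=TINY)
        assert SimulationTruth.from_dict(t.to_dict()) == t


class TestDataset:
    def test_byte_identical_under_same_seed(self):
        a = simulate_dataset(SimulationTruth(seed=5, n_individuals=TINY))
        b = simulate_dataset(SimulationTruth(seed=5, n_individuals=TINY))
        for name in ("relocations", "bearing_sets", "camera_days",
                     "vegetation", "fates"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_invariants(self, small_dataset):
        ds = small_dataset
        reloc = ds.relocations
        fates = ds.fates.set_index("individual")
        assert set(reloc["individual"]) <= set(fates.index)
        merged = reloc.join(fates["death_date"], on="individual")
        died = merged["death_date"].notna()
        assert (merged.loc[died, "date"] < merged.loc[died, "death_date"]).all()
        assert (reloc["date"] >= "2013-10-01").all()
        assert (reloc["date"] <= "2013-12-15").all()
        areas = ds.sites["area_ha"]
        assert areas.between(29, 155).all()
        pct = ds.vegetation[["warm_grass_pct", "cool_grass_pct",
                             "bare_ground_pct", "litter_pct"]]
        assert ((pct >= 0) & (pct <= 100)).all().all()

    def test_fix_rate_three_to_seven_per_week(self, small_dataset):
        reloc = small_dataset.relocations
        surv = small_dataset.fates[small_dataset.fates["death_date"].isna()]
        per_week = (reloc[reloc["individual"].isin(surv["individual"])]
                    .assign(week=lambda d: d["date"].dt.isocalendar().week)
                    .groupby(["individual", "week"]).size())
        assert per_week.between(1, 7).all()
        assert 3 <= per_week.mean() <= 7

    def test_zero_low_rate_zero_hunters(self):
        truth = SimulationTruth(seed=2, n_individuals=TINY, hunter_rate_low=0.0)
        ds = simulate_dataset(truth)
        low_sites = ds.sites.loc[ds.sites["group"] == "low", "site"]
        low = ds.camera_days[ds.camera_days["site"].isin(low_sites)]
        assert (low["n_hunters"] == 0).all()

    def test_null_effect_balanced_range_sizes(self):
        # inflation 1 / shift 0: high and low groups differ only by noise
        truth = SimulationTruth(seed=8, n_individuals={"F": {"high": 15, "low": 15}},
                                range_inflation=1.0, shift_distance=0.0,
                                harvest_hazard_coef=0.0, natural_hazard=0.0)
        ds = simulate_dataset(truth)
        reloc = ds.relocations
        spread = (reloc.groupby(["group", "individual"])[["x", "y"]]
                  .transform(lambda s: s - s.mean()))
        by_grp = spread.abs().join(reloc["group"]).groupby("group").mean().mean(axis=1)
        assert abs(np.log(by_grp["high"] / by_grp["low"])) < 0.1

    def test_early_high_pressure_exceeds_low_in_replicates(self):
        # Monte-Carlo over replicate datasets; camera generation only needs
        # a minimal population
        wins = 0
        n_rep = 100
        one = {"F": {"high": 1, "low": 1}}
        for s in range(n_rep):
            ds = simulate_dataset(SimulationTruth(seed=s, n_individuals=one))
            cams = ds.camera_days.merge(ds.sites[["site", "group"]], on="site")
            cams["season"] = cams["date"].map(classify_season)
            early = cams[cams["season"] == "early"]
            rate = early.groupby("group").apply(
                lambda g: g["n_hunters"].sum() / g["n_photos"].sum(),
                include_groups=False)
            wins += rate["high"] > rate["low"]
        assert wins >= 95

    def test_survival_monotone_in_harvest_hazard(self):
        # surviving fraction of vulnerable males decreases along a hazard grid
        fracs = []
        for coef in (0.0, 5.8, 20.0):
            alive = total = 0
            for rep in range(10):
                truth = SimulationTruth(seed=100 + rep, harvest_hazard_coef=coef,
                                        n_individuals={"M": {"high": 6}},
                                        natural_hazard=0.0)
                ds = simulate_dataset(truth)
                alive += ds.fates["death_date"].isna().sum()
                total += len(ds.fates)
            fracs.append(alive / total)
        assert fracs[0] > fracs[1] > fracs[2]

    def test_risk_response_inflates_early_spread(self):
        truth = SimulationTruth(seed=4, n_individuals={"F": {"high": 20, "low": 20}},
                                shift_distance=0.0, harvest_hazard_coef=0.0)
        ds = simulate_dataset(truth)
        reloc = ds.relocations
        reloc = reloc[reloc["season"].isin(["pre", "early"])]
        spread = (reloc.groupby(["group", "season", "individual"])[["x", "y"]]
                  .std().mean(axis=1).groupby(["group", "season"]).mean())
        ratio_high = spread[("high", "early")] / spread[("high", "pre")]
        ratio_low = spread[("low", "early")] / spread[("low", "pre")]
        assert ratio_high > ratio_low  # inflation hits only the high-risk group


class TestBearingSets:
    def test_noiseless_recovers_truth(self):
        from preyspace.telemetry import BearingSet, triangulate
        stations = np.array([[0, 0], [800, 100], [100, 900]], float)
        bs = simulate_bearing_set((400.0, 350.0), stations, kappa=50, noise=False)
        res = triangulate(BearingSet("x", None, bs["stations"], bs["azimuths_deg"]))
        assert res.estimate == pytest.approx((400.0, 350.0), abs=1e-6)

    def test_two_station_exact_intersection(self):
        from preyspace.telemetry import BearingSet, triangulate
        stations = np.array([[0, 0], [1000, 0]], float)
        bs = simulate_bearing_set((300.0, 400.0), stations, kappa=np.inf)
        res = triangulate(BearingSet("x", None, bs["stations"], bs["azimuths_deg"]))
        assert res.estimate == pytest.approx((300.0, 400.0), abs=1e-6)

    def test_coincident_station_rejected(self):
        with pytest.raises(ValueError):
            simulate_bearing_set((10.0, 10.0), [[10.0, 10.0], [0, 0]], 100)

    def test_fewer_than_two_stations_rejected(self):
        with pytest.raises(ValueError):
            simulate_bearing_set((0.0, 0.0), [[100.0, 100.0]], 100)
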