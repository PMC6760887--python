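import numpy as np
import pandas as pd
import pytest

from preyspace.synthetic import SimulationTruth, simulate_dataset

SMALL_N = {"F": {"high": 6, "low": 6}, "M": {"high": 6, "low": 6}}


@pytest.fixture(scope="session")
def small_truth() -> SimulationTruth:
    return SimulationTruth(seed=42, n_individuals=SMALL_N)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate_dataset(small_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gaussian_cloud(rng, n, sd=100.0, center=(0.0, 0.0)):
    pts = rng.normal(0.0, sd, size=(n, 2))
    return pts + np.asarray(center)


@pytest.fixture()
def reloc_frame(rng):
    """Minimal relocation table for one individual across three seasons."""
    rows = []
    for season, dates in (
        ("pre", pd.date_range("2013-10-02", "2013-10-24", freq="D")),
        ("early", pd.date_range("2013-10-28", "2013-11-20", freq="D")),
        ("late", pd.date_range("2013-11-25", "2013-12-14", freq="D")),
    ):
        for d in dates[:17]:
            x, y = rng.normal(0, 150, 2)
            rows.append({"individual": "P1", "sex": "F", "season": season,
                         "date": d, "x": x, "y": y, "site": "S01",
                         "group": "high", "year": 2013})
    return pd.DataFrame(rows)
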