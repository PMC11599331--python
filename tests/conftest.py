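import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aerospora import DailyConcentrationSeries, simulate_dataset


def make_series(values, start="2022-02-01", site="S", taxon="T", period=None):
    """Concentration series from a plain list, consecutive days from start."""
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailyConcentrationSeries(
        site=site, taxon=taxon,
        values=pd.Series(list(values), index=dates, dtype=float),
        operation_period=period,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default two-site simulation shared across tests."""
    return simulate_dataset(seed=20220201)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
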