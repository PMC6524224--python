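import numpy as np
import pandas as pd
import pytest

from netsurv.lifetable import RateTable, make_synthetic_ratetable
from netsurv.simulator import calibrate_baseline


def constant_ratetable(rate=0.01, ages=range(0, 106), years=range(1980, 2011)):
    ages = np.asarray(list(ages))
    years = np.asarray(list(years))
    grid = np.full((ages.size, years.size, 1), float(rate))
    return RateTable(ages=ages, years=years, sexes=("male",), rate=grid)


@pytest.fixture(scope="session")
def const_rt():
    return constant_ratetable(0.01)


@pytest.fixture(scope="session")
def zero_rt():
    return constant_ratetable(0.0)


@pytest.fixture(scope="session")
def synth_rt():
    return make_synthetic_ratetable()


@pytest.fixture(scope="session")
def calibrated_baseline():
    """Generalized-Weibull baseline calibrated to the 5/10/15-year anchors."""
    return calibrate_baseline()


def random_subjects(rng, n=20, with_cause=True, t_max=12.0):
    """Small random subject table inside the default table span."""
    time = rng.uniform(0.05, t_max, n).round(3)
    status = (rng.random(n) < 0.6).astype(int)
    cause = np.where(status == 1, (rng.random(n) < 0.6).astype(int), 0)
    df = pd.DataFrame({
        "id": np.arange(n),
        "time": time,
        "status": status,
        "age_dx": rng.uniform(30, 75, n),
        "sex": "male",
        "year_dx": 1990.0,
        "treatment": rng.integers(0, 2, n),
        "age_c": rng.normal(0, 8, n),
    })
    if with_cause:
        df["cause"] = cause
    return df


@pytest.fixture
def subjects_factory():
    return random_subjects
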