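import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dielocc.simulate import STUDY_CENTER, generate_landscape
from dielocc.solar import SolarProvider

TZ = dt.timezone(dt.timedelta(hours=-4))


@pytest.fixture(scope="session")
def solar() -> SolarProvider:
    return SolarProvider(**STUDY_CENTER)


@pytest.fixture(scope="session")
def small_sites() -> pd.DataFrame:
    """A 40-station synthetic landscape shared across tests."""
    return generate_landscape(n_sites=40, extent=8000, seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_sites(n: int, k: int = 10, start=dt.date(2012, 1, 5)) -> pd.DataFrame:
    """Minimal hand-built site table with constant effort k."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "site_id": [f"T{i}" for i in range(n)],
            "x": np.arange(n) * 600.0,
            "y": np.zeros(n),
            "deploy_start": [start] * n,
            "deploy_end": [start + dt.timedelta(days=k - 1)] * n,
            "Elv": rng.uniform(400, 1100, n),
            "Prk": rng.uniform(100, 20000, n),
            "NF.plot": rng.integers(0, 2, n),
            "NF250": rng.uniform(0, 1, n),
            "NF500": rng.uniform(0, 1, n),
            "Rd250": rng.uniform(0, 8, n),
            "Rd500": rng.uniform(0, 8, n),
            "Pch250": rng.uniform(0.5, 12, n),
            "Pch500": rng.uniform(0.5, 30, n),
            "Season": rng.uniform(0.1, 0.9, n),
            "Und": rng.uniform(0, 100, n),
        }
    )
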