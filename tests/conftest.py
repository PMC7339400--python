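import numpy as np
import pandas as pd
import pytest

from sedcarb import ForcingSpec, generate_forcing


@pytest.fixture(scope="session")
def default_forcing() -> pd.DataFrame:
    """Four years of default synthetic forcing, fixed seed."""
    return generate_forcing(ForcingSpec(seed=1))


@pytest.fixture
def constant_forcing() -> pd.DataFrame:
    """Flat hydrograph: constant flow, depth, temperature and loads."""
    n = 400
    return pd.DataFrame(
        {
            "date": pd.date_range("2014-01-01", periods=n, freq="D"),
            "flow": np.full(n, 4.0),
            "velocity": np.full(n, 0.5),
            "depth": np.full(n, 1.0),
            "water_temp": np.full(n, 20.0),
            "sed_yield": np.full(n, 20.0),
            "upland_poc": np.full(n, 2000.0),
            "upland_doc": np.full(n, 2500.0),
            "algal_debris": np.zeros(n),
        }
    )
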