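import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles module

from chillbreak.records_io import TemperatureSeries
from chillbreak.synthetic import SyntheticConfig, simulate_cultivar


def hourly(temps, start="2016-11-01"):
    """TemperatureSeries with hourly timestamps from `start`."""
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start, periods=len(temps), freq="h")
    return TemperatureSeries(idx, temps)


def constant_series(value, hours, start="2016-11-01"):
    return hourly(np.full(hours, float(value)), start)


@pytest.fixture(scope="session")
def small_sim():
    """One synthetic cultivar, 8 seasons — shared across tests."""
    cfg = SyntheticConfig(seed=42, n_seasons=8)
    return cfg, simulate_cultivar(cfg)
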