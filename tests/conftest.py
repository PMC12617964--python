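import numpy as np
import pandas as pd
import pytest

from infotrend import MonthlySeries


def make_series(values, start="2020-01", label="x", geography="test"):
    values = np.asarray(values, dtype=float)
    dates = pd.period_range(start, periods=len(values), freq="M")
    return MonthlySeries(dates, values, label=label, geography=geography)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def linear_series():
    """36 months rising exactly 0.5 RSV units per month."""
    return make_series(20.0 + 0.5 * np.arange(36))
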