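import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from synproc import EpochSeries

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

START = pd.Timestamp("2022-06-01 09:00")


def make_series(values, epoch_minutes=1, start=START):
    return EpochSeries(start, np.asarray(values, dtype=float), epoch_minutes)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
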