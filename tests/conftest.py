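import numpy as np
import pytest

from spiba.core import UniformSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(values, fs=10.0, units=""):
    return UniformSeries.from_rate(np.asarray(values, dtype=float), fs, units=units)
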