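import numpy as np
import pytest
from hypothesis import settings

from egfrval.metrics import BootstrapSpec, PairedSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_boot():
    """Small bootstrap for unit tests where CI precision is irrelevant."""
    return BootstrapSpec(replicates=200, seed=7)


def make_series(egfr, mgfr, name="eq"):
    return PairedSeries(np.asarray(egfr, float), np.asarray(mgfr, float), name=name)


@pytest.fixture
def identity_series():
    m = np.linspace(20.0, 120.0, 25)
    return make_series(m, m)
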