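import numpy as np
import pytest

from mblkin import (
    RateConstantSet,
    build_nitrocefin_scheme,
    default_chromophores,
)


@pytest.fixture(scope="session")
def linear_scheme():
    return build_nitrocefin_scheme("linear")


@pytest.fixture(scope="session")
def branched_scheme():
    return build_nitrocefin_scheme("branched")


@pytest.fixture(scope="session")
def chrom():
    return default_chromophores()


@pytest.fixture(scope="session")
def branched_rates():
    """Strongly branched rate set: most flux through the direct channel."""
    return RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 12.0, "k3": 4.0, "k4": 1.4})


@pytest.fixture(scope="session")
def slow_rates():
    """Identifiable branched rates: every relaxation resolvable on a 0.2-0.4 s grid."""
    return RateConstantSet({"k1": 0.02, "k-1": 0.5, "k2": 0.3, "k3": 0.2, "k4": 0.05})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
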