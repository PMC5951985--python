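import numpy as np
import pytest

from csdnet import (
    NoiseSpec,
    RunConfig,
    TimeSeriesSet,
    sample_network,
    simulate_benchmark,
)


@pytest.fixture(scope="session")
def small_network():
    """A 20-node sparse VAR(5) network used across estimation tests."""
    return sample_network(20, 0.2, order=5, seed=42)


@pytest.fixture(scope="session")
def small_benchmark(small_network):
    """One short noisy realization of the small network."""
    data = simulate_benchmark(
        small_network,
        20000,
        0.1,
        noise=NoiseSpec(kind="white", snr=5.0),
        hrf="canonical",
        seed=7,
    )
    return data


@pytest.fixture(scope="session")
def small_ts(small_benchmark):
    return TimeSeriesSet(small_benchmark.observed, dt=0.1)


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config sized for the unit-test fixtures."""
    return RunConfig(nfft=64, max_bins=3, restarts=1, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
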