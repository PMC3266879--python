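import numpy as np
import pytest

from eibstdp.spikegen import CorrelationSpec, SpikeTrainSet, generate_trains


@pytest.fixture(scope="session")
def independent_pair() -> SpikeTrainSet:
    """Two independent 10 spikes/s trains, 1000 s at 1 ms bins."""
    spec = CorrelationSpec([2], 10.0)
    return generate_trains(spec, 1e6, 1.0, seed=11)


@pytest.fixture(scope="session")
def correlated_pair() -> SpikeTrainSet:
    """Two trains with target pairwise correlation 0.25, 1000 s at 1 ms."""
    spec = CorrelationSpec([2], 10.0, within_corr=0.25)
    return generate_trains(spec, 1e6, 1.0, seed=12)


@pytest.fixture(scope="session")
def poisson_fixture_trains():
    """Sorted spike times (ms) of two independent 10 s Poisson trains."""
    rng = np.random.default_rng(5)
    pre = np.sort(rng.uniform(0, 10_000.0, rng.poisson(10 * 10)))
    post = np.sort(rng.uniform(0, 10_000.0, rng.poisson(20 * 10)))
    return pre, post
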