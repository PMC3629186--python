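import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def poisson_train(rng, rate_hz, t0_ms, t1_ms):
    n = rng.poisson(rate_hz * (t1_ms - t0_ms) * 1e-3)
    return np.sort(rng.uniform(t0_ms, t1_ms, n))
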