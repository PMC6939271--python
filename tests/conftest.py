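import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_payoffs():
    from bethedge import PayoffParams

    return PayoffParams(mu=2.0, a=0.1, b=0.9)
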