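import numpy as np
import pytest

import polypseg as ps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Small preset of the canonical architecture family, built once."""
    return ps.PolypSegNet(ps.TINY_NETWORK)


@pytest.fixture(scope="session")
def canonical_model():
    """The full 23M-parameter network (built once; forward passes in
    tests use small inputs)."""
    return ps.build_network()


@pytest.fixture(scope="session")
def synth_records():
    return ps.synth_generate(8, size=96, seed=7)
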