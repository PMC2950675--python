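import numpy as np
import pytest

from organflux.synth import generate_toy_organ


@pytest.fixture(scope="session")
def toy_organ():
    """One deterministic toy organ shared by read-only tests."""
    return generate_toy_organ(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
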