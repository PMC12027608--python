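import numpy as np
import pytest

from angioseg.synth import easy_spec, generate_pair


@pytest.fixture(scope="session")
def easy_pairs():
    """Ten high-contrast, zero-noise 64x64 phantoms (fixed seeds)."""
    return [generate_pair(easy_spec(seed=100 + i)) for i in range(10)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
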