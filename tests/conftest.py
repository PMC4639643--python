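import numpy as np
import pytest

from ssrsim import canonical_template


@pytest.fixture(scope="session")
def canonical():
    """Canonical five-component template at fs=10 kHz, 100 ms."""
    return canonical_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
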