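import numpy as np
import pytest

from svcsim.synth import gen_arena


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arena12():
    """Standard four-wall arena with 3 clustered cues per wall."""
    return gen_arena("four-wall-12")
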