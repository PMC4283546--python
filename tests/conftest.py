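import numpy as np
import pytest

from dixbone import build_head_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-sized head phantom shared by read-only tests."""
    return build_head_phantom((64, 64, 64), 3.0, 7.5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
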