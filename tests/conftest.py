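import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pair():
    """The hand-checked 6-point pair used against the brute-force oracle."""
    return [0.1, 0.5, 0.2, 0.9, 0.4, 0.7], [0.3, 0.6, 0.1, 0.8, 0.5, 0.2]
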