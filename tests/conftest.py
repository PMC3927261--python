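import numpy as np
import pytest


@pytest.fixture
def rng():
    """A fixed-seed generator so every test run draws the same streams."""
    return np.random.default_rng(20140116)


@pytest.fixture
def make_rng():
    """Factory for derived, per-case generators."""
    def _make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)
    return _make
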