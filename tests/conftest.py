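import numpy as np
import pytest

from fdcontrast.phantom import build_label_phantom


@pytest.fixture(scope="session")
def phantom48():
    """Default-resolution label phantom, shared across tests (deterministic)."""
    return build_label_phantom((48, 48, 48))


@pytest.fixture(scope="session")
def phantom32():
    """Smallest admissible phantom, for cheap cohort-level tests."""
    return build_label_phantom((32, 32, 32))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
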