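import numpy as np
import pytest

from tiltscf.sampling import build_shell_grid


@pytest.fixture(scope="session")
def coarse_grid():
    """3-degree shell grid shared by fast unit tests."""
    return build_shell_grid(3.0)


@pytest.fixture(scope="session")
def default_grid():
    """Default 1.5-degree shell grid (built once per session)."""
    return build_shell_grid(1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
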