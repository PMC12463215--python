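import numpy as np
import pytest

from paleogradient import GridSpec, make_fixtures


@pytest.fixture(scope="session")
def tiny_world():
    """Deterministic 18x9 world, 40 steps: shared read-only fixture."""
    return make_fixtures("tiny", seed=2, n_steps=40)


@pytest.fixture(scope="session")
def tiny_grid():
    return GridSpec(20.0, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
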