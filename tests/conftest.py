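import numpy as np
import pytest

from pleiosim.within_group import ModelParams


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def small_params() -> ModelParams:
    """Cheap parameter set for fast stochastic tests."""
    return ModelParams(K=30, lam=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
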