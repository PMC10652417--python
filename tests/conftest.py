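import numpy as np
import pytest
from hypothesis import settings

from cannstpp import Kernel, ModelParams, RingGrid

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid() -> RingGrid:
    return RingGrid()


@pytest.fixture(scope="session")
def plain_params() -> ModelParams:
    """Network without plasticity (alpha = beta = 0)."""
    return ModelParams()


@pytest.fixture(scope="session")
def stpp_params() -> ModelParams:
    """The canonical strong-plasticity regime."""
    return ModelParams(alpha=0.02, beta=0.1)


@pytest.fixture(scope="session")
def kernel(grid, plain_params) -> Kernel:
    return Kernel(grid, plain_params.a)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
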