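import numpy as np
import pytest

from epistrain import MechanicalParams, generate_tissue, relax, zero_stress_base


@pytest.fixture(scope="session")
def params():
    return MechanicalParams()


@pytest.fixture(scope="session")
def small_tissue():
    """A 64-cell random periodic tissue (unrelaxed)."""
    return generate_tissue(64, seed=3)


@pytest.fixture(scope="session")
def relaxed_tissue(small_tissue, params):
    return relax(small_tissue, params)


@pytest.fixture(scope="session")
def zero_stress_tissue(params):
    """A zero-net-stress 100-cell tissue shared across tests."""
    return zero_stress_base(100, seed=1, params=params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
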