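import numpy as np
import pytest

from evccp.crystal import PackingState
from evccp.energy import warm_up_kernels
from evccp.fixtures import (
    fixture_system,
    make_reference_polymorph,
    reference_ev,
    reference_minima,
)


@pytest.fixture(scope="session", autouse=True)
def _compiled_kernels():
    """Compile the numba kernels once up front."""
    warm_up_kernels()


@pytest.fixture(scope="session")
def atom_p1():
    return fixture_system("atom_p1")


@pytest.fixture(scope="session")
def bent3_p1():
    return fixture_system("bent3_p1")


@pytest.fixture(scope="session")
def bent3_p21():
    return fixture_system("bent3_p21")


@pytest.fixture(scope="session")
def bent3_ref():
    """Reference (global-minimum) polymorph of the bent3/P1 fixture."""
    return make_reference_polymorph("bent3_p1", seed=0, n=120)


@pytest.fixture(scope="session")
def bent3_minima():
    return reference_minima("bent3_p1", seed=0, n=120)


@pytest.fixture(scope="session")
def bent3_ref_ev(bent3_ref, bent3_p1):
    return reference_ev(bent3_ref, bent3_p1.mol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def dimer_state(r: float, huge: float = 80.0) -> PackingState:
    """Two Z'-molecules separated by r along x in a huge P1 cell."""
    X = np.array([[0.0, 0, 0, 0, 0, 0], [r, 0, 0, 0, 0, 0]])
    return PackingState(X, np.array([huge, huge, huge, 90.0, 90.0, 90.0]))
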