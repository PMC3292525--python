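import numpy as np
import pytest

from labeldyn.defaults import default_parameters
from labeldyn.experiments import condition_a
from labeldyn.isodynamics import IsotopomerEngine, simulate_labeling
from labeldyn.network import build_scheme


@pytest.fixture(scope="session")
def scheme_a():
    return build_scheme("A")


@pytest.fixture(scope="session")
def scheme_b():
    return build_scheme("B")


@pytest.fixture(scope="session")
def params_b(scheme_b):
    return default_parameters(scheme_b)


@pytest.fixture(scope="session")
def engine_b(scheme_b):
    return IsotopomerEngine(scheme_b)


@pytest.fixture(scope="session")
def sim_b_precise(scheme_b, params_b, engine_b):
    """One carefully converged glucose-only simulation, shared across tests."""
    return simulate_labeling(
        scheme_b, params_b, condition_a(), engine=engine_b,
        rtol=1e-8, atol=1e-12, t_eval=np.linspace(0.0, 120.0, 13),
    )
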