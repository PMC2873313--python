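import pytest

from auxinflow import Geometry, ModelParameters, Physiology, default_parameters


@pytest.fixture(scope="session")
def params():
    """Reference parameter set: published estimates, N = 20, C = 12044."""
    return default_parameters()


@pytest.fixture(scope="session")
def params_small():
    """A short file with a light molecular load, for fast stochastic tests."""
    return ModelParameters(geometry=Geometry(N=3), physiology=Physiology(),
                           C=300)


@pytest.fixture(scope="session")
def ode_long(params):
    """Deterministic solution integrated deep into the plateau."""
    from auxinflow import integrate
    return integrate(params, t_end=150000.0)
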