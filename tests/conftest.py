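import pytest
from hypothesis import settings

from fbrsim import ParameterSet, build_default_network

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def net():
    return build_default_network()


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def baseline_steady(net, params):
    """Steady state of the wound-only baseline (A0=1, B0=0, C0=0)."""
    from fbrsim import run_simulation
    return run_simulation(net, params, (1.0, 0.0, 0.0)).steady_state
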