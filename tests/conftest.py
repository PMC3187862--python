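import numpy as np
import pytest

from ectoflux import apply_scenario, load_ectoine_model


@pytest.fixture(scope="session")
def model():
    return load_ectoine_model()


@pytest.fixture(scope="session")
def synthesis_net(model):
    """Packaged model with all synthesis variants open, degradation closed."""
    return apply_scenario(model, "synthesis")


def assert_steady_state(net, solution, tol=1e-6):
    """Every optimal flux solution must satisfy S v = 0 and its bounds."""
    assert solution.optimal
    v = net.flux_array(solution.fluxes)
    S = net.stoichiometric_matrix()
    if S.size:
        assert np.max(np.abs(S @ v)) <= tol
    for r, flux in zip(net.reactions, v):
        assert r.lower_bound - tol <= flux <= r.upper_bound + tol
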