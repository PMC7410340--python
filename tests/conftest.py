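import numpy as np
import pytest

from acxsim.params import SpikingParams, ThreeUnitRateParams, TopologyParams


@pytest.fixture(scope="session")
def three_unit_params():
    return ThreeUnitRateParams()


@pytest.fixture(scope="session")
def small_spiking_params():
    """Reduced network (quarter-size populations) for fast spiking tests.

    Per-spike conductance increments are normalized by the presynaptic
    population size, so mean synaptic conductances are population-size
    invariant and the reduced network preserves the operating point of the
    full one (at higher population-rate variance).
    """
    return SpikingParams(
        topology=TopologyParams(n_exc=400, n_pv=50, n_sst=50)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
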