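import numpy as np
import pytest

import nematube as nt


@pytest.fixture(scope="session")
def params():
    """Default parameter set with zeta0 closed at the 150 Pa culture pressure."""
    return nt.ModelParams().with_zeta0_closure(150.0)


@pytest.fixture(scope="session")
def protocol():
    return nt.step_protocol()


@pytest.fixture(scope="session")
def grid():
    return np.arange(0.0, 56.0 + 1e-9, 0.5)


@pytest.fixture(scope="session")
def default_traj(params, protocol, grid):
    """The 150->650 Pa reference trajectory over 56 h."""
    return nt.integrate_tube(protocol, params, grid)


@pytest.fixture(scope="session")
def default_dataset(params):
    """Six-replicate synthetic observation set, default noise, seed 1."""
    return nt.generate_observations(params, ns=nt.NoiseSpec(seed=1))
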