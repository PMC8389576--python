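import pytest

from pamflux.protocols import kautsky_protocol, light_curve_protocol
from pamflux.simulate import GroupFactor, SimulationParams


@pytest.fixture(scope="session")
def noisefree_params() -> SimulationParams:
    return SimulationParams(noise_cv=0.0, n_per_cell=1, seed=7)


@pytest.fixture(scope="session")
def group_2x() -> GroupFactor:
    return GroupFactor("2x", 10.0)


@pytest.fixture(scope="session")
def kc_protocol():
    return kautsky_protocol()


@pytest.fixture(scope="session")
def lc_protocol():
    return light_curve_protocol()
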