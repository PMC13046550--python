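import numpy as np
import pytest

from myofatigue import ModelParameters, make_iemg_profile
from myofatigue.protocol import ProtocolSpec, simulate_protocol


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def declining_iemg():
    return make_iemg_profile("linear-decline", 60)


@pytest.fixture(scope="session")
def baseline(params, declining_iemg):
    """Full 60-cycle protocol under the declining recruitment profile,
    with dense trajectories; shared across tests that only read it."""
    spec = ProtocolSpec(iemg=declining_iemg, store_trajectory=True)
    return simulate_protocol(spec, params)


@pytest.fixture(scope="session")
def constant_max(params, declining_iemg):
    """Companion 60-cycle run with recruitment held at the initial value."""
    spec = ProtocolSpec(iemg=np.full(60, declining_iemg[0]),
                        store_trajectory=False)
    return simulate_protocol(spec, params)
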