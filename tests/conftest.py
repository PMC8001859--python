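import numpy as np
import pytest

from bupnet.engine import SimSettings
from bupnet.network import assemble_network, standard_protocol

#: loosened integrator settings for tests that check structure, not precision
FAST = SimSettings(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def fast_settings():
    return FAST


@pytest.fixture(scope="session")
def reference_system():
    return assemble_network()


@pytest.fixture(scope="session")
def reference_run_48h(reference_system):
    """Single 150 mg IR dose in the reference individual, 48 h, shared."""
    protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=48.0)
    result = reference_system.simulate(protocol, settings=FAST)
    return protocol, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
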