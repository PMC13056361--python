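import numpy as np
import pytest

from synaptoflux.datatypes import (BoutonParams, QuantalTemplate,
                                   SessionConfig, SineDCProtocol)
from synaptoflux.phmodel import protocol_single_train


@pytest.fixture(scope="session")
def protocol():
    return SineDCProtocol()


@pytest.fixture(scope="session")
def template():
    return QuantalTemplate()


@pytest.fixture
def bouton():
    return BoutonParams()


@pytest.fixture(scope="session")
def single_train_session():
    """One noisy 60-bouton control imaging session, shared across tests."""
    from synaptoflux import synthgen

    cfg = SessionConfig(seed=11, n_boutons=60, condition="control",
                        protocol=protocol_single_train())
    traces, ledger = synthgen.simulate_phluorin_session(cfg)
    return cfg, traces, ledger


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
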