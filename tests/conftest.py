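import numpy as np
import pytest

from ciona_visuomotor.circuit_model import default_circuit
from ciona_visuomotor.registration import RegistrationParams
from ciona_visuomotor.synthetic_data import CloudConfig, make_reference_cloud


@pytest.fixture(scope="session")
def circuit():
    return default_circuit()


@pytest.fixture(scope="session")
def ocellus_reference(circuit):
    """Noise-free ocellus reference cloud + ground-truth label map."""
    return make_reference_cloud(CloudConfig(region="ocellus"), circuit)


@pytest.fixture(scope="session")
def relay_reference(circuit):
    return make_reference_cloud(CloudConfig(region="relay"), circuit)


@pytest.fixture
def ocellus_params():
    return RegistrationParams(target_classes=["PR-I", "PR-II"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
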