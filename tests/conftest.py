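import numpy as np
import pytest

from rinatt import ContrastResponse, ObserverParams, OrientationPrior, ResourceGain


@pytest.fixture(scope="session")
def prior():
    return OrientationPrior.horizontal_biased()


@pytest.fixture(scope="session")
def uniform_gain():
    return ResourceGain.uniform()


@pytest.fixture(scope="session")
def mouse_observer(uniform_gain):
    """Observer in the accuracy band typical of trained mice."""
    return ObserverParams(
        gain=uniform_gain,
        cr=ContrastResponse(k_max=20.0, q=2.0, c50=0.4),
        sigma_late=8.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
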