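import numpy as np
import pytest

from lipidphase import AcquisitionParams, PakeComponent, PhaseModel


@pytest.fixture(scope="session")
def acq_default() -> AcquisitionParams:
    """Standard acquisition: 4096 points at 1 us dwell, chi = 167 kHz."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionParams:
    """Reduced acquisition for fast unit tests."""
    return AcquisitionParams(n_points=1024)


@pytest.fixture()
def single_component():
    def make(order: float, lb: float = 0.0, weight: float = 1.0) -> PhaseModel:
        return PhaseModel("test", (PakeComponent(order, lb, weight),))

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
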