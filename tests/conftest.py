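import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from marrowmrs.spectral import AcquisitionContext, default_marrow_model
from marrowmrs.synthetic import synthesize_fid, tissue_preset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return default_marrow_model()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionContext()


@pytest.fixture(scope="session")
def healthy_state():
    return tissue_preset("healthy_L5")


@pytest.fixture(scope="session")
def healthy_fid(healthy_state, model, acq):
    return synthesize_fid(healthy_state, model, acq)


@pytest.fixture(scope="session")
def wide_axis():
    """Fine, wide frequency axis for quadrature checks (Hz).

    Wide enough that the Lorentzian tails hold < 5e-4 of the area.
    """
    return np.linspace(-20_000.0, 20_000.0, 400_001)
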