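import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibromech import IndenterSpec, SynthProtocol

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def sphere_indenter():
    """Microindentation bead: 15 um diameter sphere, incompressible sample."""
    return IndenterSpec(shape="sphere", radius_um=7.5, poisson=0.5)


@pytest.fixture
def cone_indenter():
    """Nanoindentation tip: 20 deg half-angle cone, 8.5 nm tip radius."""
    return IndenterSpec(shape="cone", half_angle_deg=20.0, tip_radius_nm=8.5, poisson=0.5)


@pytest.fixture
def quiet_protocol():
    return SynthProtocol(seed=11, noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
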