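import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gustfall.bodies_aero import BodySpec, LinearDragClosure
from gustfall.scales import AIR

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def air():
    return AIR


@pytest.fixture
def dense_body():
    """Small dense test body, centre of buoyancy at the centre of gravity."""
    return BodySpec(mass=1e-6, mean_density=600.0, length=0.01,
                    inertia=np.diag([1e-11, 1e-11, 1e-11]))


@pytest.fixture
def bottom_heavy_body():
    """Dandelion-like eccentric body: centre of buoyancy above the CG."""
    return BodySpec(mass=0.8e-6, mean_density=400.0, length=0.014,
                    inertia=np.diag([2e-11, 2e-11, 2e-11]),
                    eccentricity=5e-3, r_hat=np.array([1.0, 0.0, 0.0]))


@pytest.fixture
def linear_closure_ut038(dense_body, air):
    """Linear drag tuned so the dense body settles at 0.38 m/s."""
    c = dense_body.mass * dense_body.reduced_gravity_in(air) / 0.38
    return LinearDragClosure(c=c, c_omega=1e-12)
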