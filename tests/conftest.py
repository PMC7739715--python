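import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from adipoquant.petkin import KineticParams, build_frame_schedule
from adipoquant.phantoms import FengParams, PhantomSpec, generate_phantom, simulate_input_function


@pytest.fixture(scope="session")
def schedule():
    """The 26-frame (12x10 s, 4x120 s, 10x300 s) dynamic schedule."""
    return build_frame_schedule()


@pytest.fixture(scope="session")
def feng_if():
    """Default tri-exponential blood curve densely sampled over 60 min."""
    return simulate_input_function(FengParams(), np.arange(0.0, 60.01, 0.1))


@pytest.fixture(scope="session")
def feng_if_long():
    """Same blood curve sampled out to 120 min for late static simulations."""
    return simulate_input_function(FengParams(), np.arange(0.0, 120.01, 0.1))


@pytest.fixture(scope="session")
def reference_params():
    """Adipose-like irreversible 2TCM parameters with Ki = 0.0096774."""
    return KineticParams(0.05, 0.25, 0.06, 0.0)


@pytest.fixture(scope="session")
def noiseless_annulus():
    """Noiseless annulus phantom: SAT between radii 80 and 95 mm."""
    spec = PhantomSpec(
        n_slices=2, body_radius_mm=95.0, sat_thickness_mm=15.0,
        internal_fat_fraction=0.0, bias_amplitude=0.0, noise_sd=0.0, seed=0,
    )
    return spec, generate_phantom(spec, "abdomen")


@pytest.fixture(scope="session")
def default_abdomen():
    """Default noisy, biased abdominal phantom (the realistic test case)."""
    spec = PhantomSpec(seed=1)
    return spec, generate_phantom(spec, "abdomen")
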