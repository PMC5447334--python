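import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import awplan as aw
from awplan.phantom import PhantomConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def small_phantom_config(**overrides) -> PhantomConfig:
    """A reduced torso phantom (128 x 128 x 96 mm) for fast unit tests."""
    kw = dict(
        volume_shape=(64, 64, 48),
        spacing_mm=(2.0, 2.0, 2.0),
        body_half_axes_mm=(52.0, 42.0),
        organ_center_mm=(0.0, 8.0, 0.0),
        organ_half_axes_mm=(26.0, 18.0, 22.0),
        rib_count=3,
        seed=7,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    ct, labels, targets = aw.generate_phantom(small_phantom_config(), n_targets=5)
    return ct, labels, targets


@pytest.fixture(scope="session")
def small_surface(small_phantom):
    ct, _, _ = small_phantom
    mask = aw.extract_body_mask(ct)
    return aw.extract_surface_points(mask, ct, density_per_mm2=0.02)


@pytest.fixture(scope="session")
def small_field(small_phantom):
    ct, _, _ = small_phantom
    return aw.hu_to_mu(ct)


@pytest.fixture(scope="session")
def test_probe():
    """Reduced scan-line count keeps exhaustive searches fast."""
    return aw.ProbeGeometry(n_elements=16, array_radius_mm=40.0, fov_deg=70.0, depth_mm=140.0)


@pytest.fixture(scope="session")
def planner_config():
    return aw.PlannerConfig(angle_step_deg=15.0, ray_step_mm=2.0)
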