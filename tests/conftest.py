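import numpy as np
import pytest

from nutriface.geometry import LandmarkSet
from nutriface.synthetic import SimConfig, generate_cohort
from nutriface.synthetic import _template_landmarks


@pytest.fixture
def template_landmarks() -> np.ndarray:
    """Canonical face template scaled to a 320 px canvas, (68, 2) array."""
    return _template_landmarks() * 320.0


@pytest.fixture
def landmarks68(template_landmarks) -> LandmarkSet:
    return LandmarkSet(template_landmarks)


@pytest.fixture
def clean_config() -> SimConfig:
    """Generator config with every nuisance source switched off."""
    return SimConfig(
        noise_sd=0.0,
        max_rotation_deg=0.0,
        jitter=0.0,
        scale_jitter=0.0,
        mouth_jitter=False,
        n_shadow_blobs=0,
        illum_grad=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject cohort shared across smoke tests (seeded)."""
    return generate_cohort(SimConfig(n=40, seed=7))
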