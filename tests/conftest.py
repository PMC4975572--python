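import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fibreorder as fo

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_cylinder() -> fo.CylinderModel:
    """Canonical axis-aligned cylinder used by hand-computed examples."""
    return fo.CylinderModel(
        origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]), radius=10.0, length=100.0
    )


@pytest.fixture
def edl_cylinder() -> fo.CylinderModel:
    """Cylinder at the default synthetic fibre scale (R = 20 µm, L = 500 µm)."""
    return fo.CylinderModel(
        origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]), radius=20.0, length=500.0
    )
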