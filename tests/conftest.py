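import numpy as np
import pytest

from picowash import PlugGeometry, Roi, build_scene


@pytest.fixture
def default_scene():
    """Operating point of the study: 85 μm plugs, 2 mL/h, 60 x 50 μm channel."""
    return build_scene({}, seed=1)


@pytest.fixture
def washed_scene():
    """One washer of ground-truth fold dilution 4 in the default channel."""
    return build_scene(
        {"washers": [{"position_um": 300.0, "stage_dilution": 4.0, "gradient_span_um": 30.0}]},
        seed=1,
    )


@pytest.fixture
def full_roi():
    return Roi(0, 50, 0, 600)


@pytest.fixture
def equal_geometry():
    """Plug train with equal plug length and spacing (duty fraction 0.5)."""
    return PlugGeometry(L_drop=85.0, L_space=85.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
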