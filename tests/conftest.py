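import pytest

from discflow import default_geometry, water_properties
from discflow.hydraulics import hydrostatic_pressure
from discflow.perfusion_model import FlowModelSpec, omega0_from_burst
from discflow.synthetic_data import calibrated_truth


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def water37():
    return water_properties(37.0)


@pytest.fixture(scope="session")
def truth_97(geom, water37):
    """Pinned-model truth with burst pressure exactly 97 Pa and the flow
    coefficient calibrated through the (100 rpm, 97 μl/h), (200 rpm,
    445 μl/h) reference points."""
    p_h = hydrostatic_pressure(water37, geom.head_height)
    omega0 = omega0_from_burst(97.0, p_h, water37, geom.r_inner, geom.r_outer)
    return FlowModelSpec("combined_pinned", B=calibrated_truth().B, omega0=omega0)


@pytest.fixture(scope="session")
def calibrated_spec():
    """Pinned model interpolating the two reference measurements exactly."""
    return calibrated_truth()
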