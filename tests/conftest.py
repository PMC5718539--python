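import pytest

from epidiso import SimulationTruth, render_view
from epidiso.measurement import detect_edges

OFFSET = (1.5, -0.8, 0.5)


@pytest.fixture(scope="session")
def truth_offset():
    return SimulationTruth(phantom_offset_mm=OFFSET, seed=3)


@pytest.fixture(scope="session")
def truth_zero():
    return SimulationTruth(seed=1)


@pytest.fixture(scope="session")
def view_ap(truth_offset):
    """Gantry 0 / collimator 90 image with a known phantom offset."""
    return render_view(truth_offset, 0.0, 90.0)


@pytest.fixture(scope="session")
def edges_ap(view_ap):
    return detect_edges(view_ap)


@pytest.fixture(scope="session")
def view_zero(truth_zero):
    return render_view(truth_zero, 0.0, 90.0)


@pytest.fixture(scope="session")
def edges_zero(view_zero):
    return detect_edges(view_zero)


@pytest.fixture(scope="session")
def quiet_truth():
    """Noise-free truth for subpixel-accuracy checks."""
    return SimulationTruth(phantom_offset_mm=OFFSET, noise_sd=0.0, seed=3)
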