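import pytest

import trunkload as tl


@pytest.fixture
def geom():
    """Bench wood-pole geometry: 0.01 m diameter, gauges at 0.1/0.3 m."""
    return tl.WOOD_POLE


@pytest.fixture
def layout():
    """Misaligned layout with heterogeneous apparent E (calibrated-pole values)."""
    return tl.TABLE2_WOOD_POLE_LAYOUT


@pytest.fixture
def true_cals(layout):
    """The layout's ground truth expressed as perfect calibrations."""
    return layout.as_calibrations()
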