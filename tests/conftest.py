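from datetime import datetime

import numpy as np
import pytest
from hypothesis import settings

from fearcurve import CurveParams, DetectionEvent
from fearcurve.synthetic_data import simulate_response_data

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Fitted parameters for all species combined (y0, sensitivity, discount).
COMBINED = CurveParams(0.724, 5.00, 0.784)


def ev(camera, ts, subject, n=1):
    return DetectionEvent(camera, datetime.fromisoformat(ts), subject, n)


@pytest.fixture
def combined_params():
    return COMBINED


@pytest.fixture
def arps_curve():
    """A response curve simulated from the combined-taxa Arps parameters:
    2000 camera-days per level over levels 0..15."""
    return simulate_response_data(COMBINED, "arps", range(16), 2000, rng=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
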