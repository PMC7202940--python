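"""Shared fixtures: small rendered stacks and fitted trackers.

Unit tests run on a 100 px ROI with a short calibration ramp to stay fast;
the acceptance tests build their own full-scale protocol runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from phasortrack import protocols
from phasortrack.phasor import build_reference_set
from phasortrack.tracking import PhasorTracker


@pytest.fixture(scope="session")
def model():
    return protocols.standard_model()


@pytest.fixture(scope="session")
def small_refs():
    """Four log-spaced reference periods on a 100 px ROI."""
    return build_reference_set(100, protocols.log_spaced_periods(4))


@pytest.fixture(scope="session")
def small_ramp(model):
    """Float (unquantized) calibration ramp, 100 px ROI, 6..14 um."""
    stack, z = protocols.render_calibration_stack(
        model, roi_size=100, z_lo_nm=6_000, z_hi_nm=14_000, n_frames=161,
        quantize=False,
    )
    return stack, z


@pytest.fixture(scope="session")
def fitted_tracker(small_ramp):
    """PhasorTracker calibrated on the small float ramp (order 5)."""
    stack, z = small_ramp
    est = PhasorTracker(n_periods=4, poly_order=5, fit_range=(7_000, 13_000))
    return est.fit(stack, z)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
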