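"""Shared fixtures: small ring configurations that keep simulations fast."""

import numpy as np
import pytest

from ringbeam.arraygeom import RingArray, make_grid
from ringbeam.echosim import ScattererSet, make_pulse, simulate_rf_frame


@pytest.fixture(scope="session")
def tiny_array():
    """4-element ring for brute-force oracle comparisons."""
    return RingArray(4, 20.0, 2.0e6, 16.0e6)


@pytest.fixture(scope="session")
def small_array():
    """16-element ring, small enough for second-scale simulations."""
    return RingArray(16, 25.0, 2.0e6, 16.0e6)


@pytest.fixture(scope="session")
def small_pulse():
    return make_pulse(2.0e6, 3, 16.0e6)


@pytest.fixture(scope="session")
def point_frame(small_array, small_pulse):
    """Noise-free frame of a single off-center point target at 1500 m/s."""
    scat = ScattererSet(np.array([[1.5, -2.0, 0.0]]), np.array([1.0]))
    return simulate_rf_frame(small_array, scat, 1500.0, small_pulse)


@pytest.fixture(scope="session")
def small_grid(small_array):
    return make_grid(-4.0, 4.0, -5.0, 3.0, 0.1, ring_radius=small_array.radius)


@pytest.fixture(scope="session")
def recovery_setup():
    """Full-scale ring and the lateral-group ROI for speed-recovery checks.

    Coherence autofocus needs the aperture sampling of the full 128-element,
    110 mm ring; sparser rings alias the carrier-period ambiguity ("teeth"
    in the objective) onto wrong candidates. The ROI is an 8 x 8 mm window
    over the lateral wire group at 0.1 mm pixels.
    """
    from ringbeam.echosim import make_resolution_phantom

    array = RingArray(128, 110.0, 3.0e6, 40.0e6)
    grid = make_grid(-4.0, 4.0, 6.0, 14.0, 0.1, ring_radius=array.radius)
    pulse = make_pulse(3.0e6, 5, 40.0e6)
    phantom = make_resolution_phantom()
    return array, grid, pulse, phantom
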