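import numpy as np
import pytest

from pbirecon.core import Geometry, ScanMode
from pbirecon.simulator import EllipseSpec

PIXEL = 3.05e-6


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def beamline_geometry():
    """40 keV, 2.2 m propagation, 3.05 um pixels, single view."""
    return Geometry(
        energy=40.0,
        pixel_size=PIXEL,
        distance=2.2,
        angles=[0.0],
        axis_position=127.5,
    )


@pytest.fixture
def scan_geometry():
    """Conventional 180-degree scan, 180 views, 128-column detector."""
    return Geometry(
        energy=40.0,
        pixel_size=PIXEL,
        distance=0.0,
        angles=np.linspace(0.0, 180.0, 180, endpoint=False),
        axis_position=63.5,
    )


@pytest.fixture
def absorption_ellipses():
    """Small absorbing phantom fitting a 128-column detector."""
    return [
        EllipseSpec(0, 0, 40 * PIXEL, 40 * PIXEL, 0, beta_value=3.0e-9),
        EllipseSpec(12 * PIXEL, -8 * PIXEL, 10 * PIXEL, 16 * PIXEL, 20.0,
                    beta_value=1.5e-9),
    ]


@pytest.fixture
def half_acquisition_set():
    """Offset-axis 360-degree scan with known ground-truth axis (72.5 px)."""
    from pbirecon.simulator import simulate_half_acquisition

    geom = Geometry(
        energy=40.0,
        pixel_size=PIXEL,
        distance=0.0,
        angles=np.linspace(0.0, 360.0, 240, endpoint=False),
        axis_position=0.0,
        scan_mode=ScanMode.FULL_TURN_360_OFFSET,
    )
    ells = [
        EllipseSpec(0, 0, 50 * PIXEL, 50 * PIXEL, 0, beta_value=1.0e-9),
        EllipseSpec(20 * PIXEL, 10 * PIXEL, 15 * PIXEL, 25 * PIXEL, 40.0,
                    beta_value=1.0e-9),
        EllipseSpec(-25 * PIXEL, -10 * PIXEL, 10 * PIXEL, 10 * PIXEL, 0,
                    beta_value=2.0e-9),
    ]
    ps = simulate_half_acquisition(ells, geom, axis_offset=25.0,
                                   detector_width=96, height=2)
    return ps, ells, 25.0
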