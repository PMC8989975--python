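import numpy as np
import pytest

from fusulm import AcquisitionConfig, VesselPath


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fus_config():
    """Functional acquisition: 200-frame blocks at 500 Hz."""
    return AcquisitionConfig(
        framerate=500.0, block_size=200, n_blocks=1,
        prf=5500.0, angles_deg=tuple(np.linspace(-10, 10, 10)),
    )


@pytest.fixture
def ulm_config():
    """ULM acquisition: 400-frame blocks at 1000 Hz, 5 angles at 5 kHz PRF."""
    return AcquisitionConfig(
        framerate=1000.0, block_size=400, n_blocks=1,
        prf=5000.0, angles_deg=(-5.0, -2.0, 0.0, 2.0, 5.0),
    )


@pytest.fixture
def straight_vessels():
    """Three well-separated, non-crossing vessels in a 6.4 x 6.4 mm field,
    speeds inside the 9-20 mm/s range, one flowing in the opposite
    direction."""
    return [
        VesselPath(((1.2, 0.3), (1.5, 6.1)), flow_speed=12.0, radius=0.02, direction=1),
        VesselPath(((3.3, 0.3), (3.0, 6.1)), flow_speed=16.0, radius=0.02, direction=-1),
        VesselPath(((5.2, 0.3), (5.4, 6.1)), flow_speed=9.5, radius=0.02, direction=1),
    ]


def gaussian_blob(shape, z0_px, x0_px, sigma_px, amplitude=1.0):
    """Synthetic PSF blob with its centre at pixel coordinates (z0, x0)."""
    zz = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    return amplitude * np.exp(-((zz - z0_px) ** 2 + (xx - x0_px) ** 2) / (2 * sigma_px**2))
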