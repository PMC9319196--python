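import numpy as np
import pytest

from lfdeconv import OpticalConfig, phase_space_psf


@pytest.fixture(scope="session")
def small_cfg():
    """5x5-angle system with a short z-stack; cheap enough for oracle tests."""
    return OpticalConfig(
        n_u=5,
        lens_pitch=50.0,
        ds=10.0,
        n_x_psf=5,
        z_planes=np.array([-9.0, -3.0, 3.0, 9.0]),
    )


@pytest.fixture(scope="session")
def small_psf(small_cfg):
    return phase_space_psf(small_cfg)


@pytest.fixture(scope="session")
def tiny_cfg():
    """3x3-angle system with 8 z-planes for deeper-stack oracle checks."""
    return OpticalConfig(
        n_u=3,
        lens_pitch=30.0,
        ds=10.0,
        n_x_psf=5,
        z_planes=np.linspace(-10.5, 10.5, 8),
    )


@pytest.fixture(scope="session")
def tiny_psf(tiny_cfg):
    return phase_space_psf(tiny_cfg)


@pytest.fixture(scope="session")
def full_cfg_z8():
    """Full-scale 13x13-angle system, 8 z-planes (point-source recovery)."""
    return OpticalConfig(n_u=13, n_x_psf=9, z_planes=np.linspace(-14.0, 14.0, 8))


@pytest.fixture(scope="session")
def full_psf_z8(full_cfg_z8):
    return phase_space_psf(full_cfg_z8)


@pytest.fixture(scope="session")
def full_cfg_z16():
    """Full-scale 13x13-angle system, 16 z-planes (noise benchmark)."""
    return OpticalConfig(n_u=13, n_x_psf=9, z_planes=np.linspace(-15.0, 15.0, 16))


@pytest.fixture(scope="session")
def full_psf_z16(full_cfg_z16):
    return phase_space_psf(full_cfg_z16)
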