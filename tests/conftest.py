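import numpy as np
import pytest

from cfcnn.phantoms import PhantomConfig, generate_phantom
from cfcnn.volumes import CtVolume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free isolated sphere: the canonical easy case.

    A half-integer radius avoids the single-voxel pole slice of integer
    radii, whose area ratio would (correctly) trip the propagation stop
    rule and shave the poles off the reconstruction.
    """
    return generate_phantom(
        PhantomConfig(nodule_kind="isolated", radius_vox=6.5, noise_sd=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomConfig(nodule_kind="isolated", seed=3))


@pytest.fixture()
def ramp_volume():
    """A volume whose intensity is a distinct linear ramp along each axis."""
    z, y, x = np.meshgrid(
        np.arange(24), np.arange(48), np.arange(48), indexing="ij"
    )
    vox = 1.0 * z + 7.0 * y + 131.0 * x
    return CtVolume(voxels=vox, spacing=(2.0, 0.7, 0.7), volume_id="ramp")
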