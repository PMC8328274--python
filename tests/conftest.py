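import numpy as np
import pytest

from plexuscount import FixtureParams, IntensityImage


def gaussian_blob_image(
    shape, centers, amplitude=200.0, sd=4.0, background=5.0, rho=1.0
) -> IntensityImage:
    """Sum of isotropic Gaussian bumps on a constant background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(background))
    for r, c in centers:
        img += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sd * sd))
    return IntensityImage(img, rho)


@pytest.fixture
def rng():
    return np.random.default_rng(20210723)


@pytest.fixture
def small_fixture_params():
    """A compact synthetic micrograph that the pipeline recovers exactly."""
    return FixtureParams(
        image_shape=(700, 700),
        rho=1.5,
        n_ganglia=4,
        sizes=[3, 5, 8, 13],
        n_extraganglionic=2,
        seed=7,
    )
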