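import numpy as np
import pytest

from ccmorph.phantom import PhantomSpec, generate_phantom_2d, generate_phantom_3d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def flat_spec_2d():
    """Degenerate 2D spec: flat band, no noise, no voids."""
    return PhantomSpec(
        shape=(64, 96),
        base_thickness_px=12.0,
        amplitude_px=0.0,
        interface_roughness_px=0.0,
        noise_sd=0.0,
        void_density_per_1000px=0.0,
    )


@pytest.fixture(scope="session")
def flat_phantom_2d(flat_spec_2d):
    return generate_phantom_2d(flat_spec_2d)


@pytest.fixture(scope="session")
def small_phantom_3d():
    spec = PhantomSpec(
        shape=(48, 48, 48),
        base_thickness_px=14.0,
        amplitude_px=2.0,
        spatial_period_px=48.0,
        noise_sd=0.02,
        void_density_per_1000px=0.2,
        seed=7,
    )
    return generate_phantom_3d(spec)


def random_blob_mask(rng, shape, density=0.5, max_foreground=None):
    """Random blobby binary mask (smoothed noise thresholded), never empty."""
    from scipy import ndimage

    while True:
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        mask = noise > np.quantile(noise, 1.0 - density)
        if max_foreground is not None and mask.sum() > max_foreground:
            density *= 0.7
            continue
        if mask.any():
            return mask
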