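import numpy as np
import pytest

from ccmorph.grids import GridMetadata
from ccmorph.phantom import (
    PhantomSpec,
    generate_phantom_2d,
    generate_phantom_3d,
    prescribed_mean_thickness_um,
)


def band_heights(mask2d):
    return mask2d.sum(axis=0)


class TestSpecValidation:
    def test_band_must_never_vanish(self):
        with pytest.raises(ValueError, match="vanish"):
            PhantomSpec(shape=(64, 64), base_thickness_px=5, amplitude_px=4)

    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="cartilage < cc < bone"):
            PhantomSpec(shape=(64, 64), intensity_means=(0.5, 0.4, 0.9))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom_2d(PhantomSpec(shape=(16, 16, 16)))
        with pytest.raises(ValueError):
            generate_phantom_3d(PhantomSpec(shape=(64, 64)))


class TestGeometry2D:
    def test_flat_spec_gives_exact_slab(self, flat_phantom_2d, flat_spec_2d):
        h = band_heights(flat_phantom_2d.truth_mask.values)
        assert np.all(h == round(flat_spec_2d.base_thickness_px))

    def test_truth_band_follows_sinusoid(self):
        spec = PhantomSpec(
            shape=(96, 256), base_thickness_px=20, amplitude_px=8, spatial_period_px=128,
            noise_sd=0.0, void_density_per_1000px=0.0,
        )
        sample = generate_phantom_2d(spec)
        x = np.arange(256)
        expected = 20 + 8 * np.sin(2 * np.pi * x / 128)
        assert np.all(np.abs(band_heights(sample.truth_mask.values) - expected) <= 1)

    def test_truth_extent_matches_thickness_field(self, rng):
        spec = PhantomSpec(shape=(96, 128), base_thickness_px=15, amplitude_px=5,
                           interface_roughness_px=2.0, seed=42)
        sample = generate_phantom_2d(spec)
        h = band_heights(sample.truth_mask.values)
        assert np.all(np.abs(h - sample.thickness_field_px) <= 1)

    def test_voids_stay_inside_band_and_truth_keeps_them(self):
        spec = PhantomSpec(shape=(96, 192), base_thickness_px=24,
                           void_density_per_1000px=5.0, noise_sd=0.0, seed=3)
        sample = generate_phantom_2d(spec)
        img, mask = sample.image.intensities, sample.truth_mask.values
        cart, cc, bone = spec.intensity_means
        dark_in_band = mask & (img < cc - 0.1)
        assert dark_in_band.sum() > 0  # voids exist and are inside the band
        h = band_heights(mask)
        assert np.all(np.abs(h - np.round(sample.thickness_field_px)) <= 1)

    def test_phase_separability_at_zero_noise(self):
        spec = PhantomSpec(shape=(64, 96), noise_sd=0.0, void_density_per_1000px=0.0,
                           base_thickness_px=16, seed=5)
        sample = generate_phantom_2d(spec)
        img, mask = sample.image.intensities, sample.truth_mask.values.astype(bool)
        cart, cc, bone = spec.intensity_means
        z = np.arange(img.shape[0])[:, None]
        top = mask.argmax(axis=0)[None]
        above, below = z < top, z >= top + band_heights(mask)[None]
        assert np.all(img[above] == cart)
        assert np.all(img[mask] == cc)
        assert img[below].min() > cc  # bone strictly brighter than the band


class TestDeterminism:
    def test_same_seed_bit_identical_2d(self, flat_spec_2d):
        a = generate_phantom_2d(flat_spec_2d)
        b = generate_phantom_2d(flat_spec_2d)
        assert np.array_equal(a.image.intensities, b.image.intensities)
        assert np.array_equal(a.truth_mask.values, b.truth_mask.values)

    def test_same_seed_bit_identical_3d(self, small_phantom_3d):
        again = generate_phantom_3d(small_phantom_3d.spec)
        assert np.array_equal(small_phantom_3d.image.intensities, again.image.intensities)

    def test_seed_changes_noise_not_geometry(self):
        base = dict(shape=(64, 96), base_thickness_px=14, amplitude_px=3,
                    interface_roughness_px=0.0, void_density_per_1000px=0.0, noise_sd=0.05)
        a = generate_phantom_2d(PhantomSpec(**base, seed=1))
        b = generate_phantom_2d(PhantomSpec(**base, seed=2))
        assert np.array_equal(a.truth_mask.values, b.truth_mask.values)
        assert not np.array_equal(a.image.intensities, b.image.intensities)


class TestGeometry3D:
    def test_flat_3d_spec_gives_constant_slab(self):
        spec = PhantomSpec(shape=(48, 32, 32), base_thickness_px=10, amplitude_px=0.0,
                           noise_sd=0.0, void_density_per_1000px=0.0)
        sample = generate_phantom_3d(spec)
        h = sample.truth_mask.values.sum(axis=0)
        assert np.all(h == 10)

    def test_mean_thickness_field_matches_base_over_whole_periods(self):
        spec = PhantomSpec(shape=(48, 64, 64), base_thickness_px=12, amplitude_px=4,
                           spatial_period_px=32, noise_sd=0.0, void_density_per_1000px=0.0)
        sample = generate_phantom_3d(spec)
        assert sample.thickness_field_px.mean() == pytest.approx(12, rel=0.02)


class TestPrescribedThickness:
    def test_flat_base_times_pixel_size(self):
        spec = PhantomSpec(shape=(48, 32), base_thickness_px=10, amplitude_px=0.0,
                           noise_sd=0.0, void_density_per_1000px=0.0)
        sample = generate_phantom_2d(spec)
        assert prescribed_mean_thickness_um(sample, GridMetadata(pixel_size_um=3.2)) == pytest.approx(32.0)

    def test_sinusoid_averages_out_over_whole_periods(self):
        spec = PhantomSpec(shape=(96, 256), base_thickness_px=20, amplitude_px=8,
                           spatial_period_px=128, noise_sd=0.0, void_density_per_1000px=0.0)
        sample = generate_phantom_2d(spec)
        got = prescribed_mean_thickness_um(sample, GridMetadata(pixel_size_um=2.56))
        assert got == pytest.approx(51.2, abs=1e-9)

    def test_empty_field_rejected(self, flat_phantom_2d):
        import dataclasses

        broken = dataclasses.replace(flat_phantom_2d, thickness_field_px=np.array([]))
        with pytest.raises(ValueError):
            prescribed_mean_thickness_um(broken, GridMetadata())
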