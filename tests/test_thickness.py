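import numpy as np
import pytest
from scipy import ndimage

from ccmorph.grids import BinaryMask, GridMetadata
from ccmorph.thickness import (
    ThicknessMap,
    brute_force_thickness,
    local_thickness,
    sample_mean_thickness,
    summarize,
)
from conftest import random_blob_mask


def slab_mask(h, shape=(60, 80), top=20):
    m = np.zeros(shape, dtype=bool)
    m[top : top + h, :] = True
    return m


class TestDefinition:
    @pytest.mark.parametrize("h", [4, 10, 24])
    def test_slab_thickness_equals_height_away_from_ends(self, h):
        m = slab_mask(h, shape=(h + 20, 4 * h), top=8)
        tau = local_thickness(m).values
        interior = m.copy()
        interior[:, :h] = interior[:, -h:] = False
        assert np.all(tau[interior] == h)
        assert np.all(tau[m] <= h)  # lateral ends are clipped, never inflated
        assert np.all(tau[~m] == 0)

    def test_single_pixel_has_thickness_two(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert local_thickness(m).values[4, 4] == 2.0

    def test_thickness_at_least_twice_the_distance_transform(self, rng):
        for _ in range(10):
            m = random_blob_mask(rng, (40, 40))
            tau = local_thickness(m).values
            padded = np.pad(m, 1)
            edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
            assert np.all(tau[m] >= 2 * edt[m] - 1e-12)

    def test_dilation_never_decreases_thickness(self, rng):
        m = random_blob_mask(rng, (36, 36))
        dilated = ndimage.binary_dilation(m)
        t0 = local_thickness(m).values
        t1 = local_thickness(dilated).values
        assert np.all(t1[m] >= t0[m])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            local_thickness(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="non-empty"):
            brute_force_thickness(np.zeros((8, 8), dtype=bool))

    def test_brute_force_guard(self):
        with pytest.raises(ValueError, match="guard"):
            brute_force_thickness(np.ones((150, 150), dtype=bool))


class TestOracleEquivalence:
    """The production path must equal the literal definition bitwise."""

    def test_random_2d_masks(self, rng):
        for _ in range(30):
            m = random_blob_mask(rng, (32, 32), density=rng.uniform(0.2, 0.7))
            fast = local_thickness(m).values
            ref = brute_force_thickness(m).values
            assert np.array_equal(fast, ref)

    def test_random_3d_masks(self, rng):
        for _ in range(5):
            m = random_blob_mask(rng, (16, 16, 16), density=0.4)
            assert np.array_equal(local_thickness(m).values, brute_force_thickness(m).values)

    def test_sparse_scatter_masks(self, rng):
        m = rng.random((48, 48)) < 0.05
        m[0, 0] = True
        assert np.array_equal(local_thickness(m).values, brute_force_thickness(m).values)


class TestSummaries:
    def test_constant_map(self):
        vals = np.zeros((10, 10))
        vals[2:5, 2:5] = 10.0
        s = summarize(ThicknessMap(vals, GridMetadata(pixel_size_um=3.2)))
        assert (s.mean_um, s.median_um, s.max_um, s.sd_um) == (32.0, 32.0, 32.0, 0.0)
        assert s.n_foreground == 9

    def test_two_value_map_population_sd(self):
        vals = np.array([[2.0, 4.0]])
        s = summarize(ThicknessMap(vals, GridMetadata(pixel_size_um=1.0)))
        assert (s.mean_um, s.median_um, s.max_um, s.sd_um) == (3.0, 3.0, 4.0, 1.0)

    def test_micrometre_outputs_scale_with_pixel_size(self):
        vals = np.array([[1.0, 3.0, 5.0]])
        s1 = summarize(ThicknessMap(vals, GridMetadata(pixel_size_um=1.0)))
        s3 = summarize(ThicknessMap(vals, GridMetadata(pixel_size_um=3.0)))
        for attr in ("mean_um", "median_um", "max_um", "sd_um"):
            assert getattr(s3, attr) == pytest.approx(3 * getattr(s1, attr))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            summarize(ThicknessMap(np.zeros((4, 4)), GridMetadata()))

    @pytest.mark.parametrize("h", [4, 10, 24])
    def test_slab_interior_mean_is_exact(self, h):
        m = slab_mask(h, shape=(h + 20, 4 * h), top=8)
        tau = local_thickness(m).values
        interior = m.copy()
        interior[:, :h] = interior[:, -h:] = False
        s = summarize(ThicknessMap(np.where(interior, tau, 0.0), GridMetadata(pixel_size_um=3.2)))
        assert s.mean_um == h * 3.2
        assert s.sd_um == 0.0

    def test_sample_mean_is_unweighted_and_order_free(self):
        a = summarize(ThicknessMap(np.array([[30.0]]), GridMetadata(pixel_size_um=1.0)))
        b = summarize(ThicknessMap(np.array([[50.0]]), GridMetadata(pixel_size_um=1.0)))
        assert sample_mean_thickness([a, b]) == 40.0
        assert sample_mean_thickness([b, a]) == 40.0
        assert sample_mean_thickness([a]) == 30.0
        with pytest.raises(ValueError):
            sample_mean_thickness([])


class TestPhantomRecovery:
    def test_truth_mask_thickness_matches_prescription_3d(self, small_phantom_3d):
        from ccmorph.phantom import prescribed_mean_thickness_um

        meta = small_phantom_3d.image.meta
        got = summarize(local_thickness(small_phantom_3d.truth_mask), meta.pixel_size_um)
        want = prescribed_mean_thickness_um(small_phantom_3d, meta)
        assert abs(got.mean_um - want) / want <= 0.05
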