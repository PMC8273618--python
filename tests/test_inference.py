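import numpy as np
import pytest

from ccmorph.grids import ImageVolume
from ccmorph.inference import (
    InferenceConfig,
    TileSpec,
    predict_2d,
    predict_volume,
    stitch,
    threshold_probability,
    tile_image,
)


class ConstantModel:
    """Stand-in fold model predicting a fixed probability everywhere."""

    def __init__(self, value):
        self.value = value

    def predict(self, tile):
        return np.full_like(np.asarray(tile, dtype=float), self.value)


class PointwiseModel:
    """Deterministic tile-wise function of intensity (no spatial context)."""

    def predict(self, tile):
        return np.clip(0.2 + 0.6 * np.asarray(tile, dtype=float), 0, 1)


class TestTiling:
    def test_window_sized_image_is_single_tile(self):
        img = np.random.default_rng(0).random((512, 1024))
        tiles, origins, pad = tile_image(img, TileSpec())
        assert origins == [(0, 0)] and pad == (0, 0)
        assert np.array_equal(tiles[0], img)

    def test_default_spec_on_1024x2048_gives_nine_tiles(self):
        tiles, origins, _ = tile_image(np.zeros((1024, 2048)), TileSpec())
        assert len(tiles) == 9
        assert sorted({r for r, _ in origins}) == [0, 256, 512]
        assert sorted({c for _, c in origins}) == [0, 512, 1024]

    def test_final_windows_shift_inward_not_past_bounds(self):
        spec = TileSpec(window=(64, 64), step=(48, 48))
        _, origins, _ = tile_image(np.zeros((100, 150)), spec)
        for r, c in origins:
            assert r + 64 <= 100 and c + 64 <= 150
        assert (100 - 64, 150 - 64) in origins

    def test_small_image_reflect_padded_to_window(self):
        spec = TileSpec(window=(64, 64), step=(32, 32))
        tiles, origins, pad = tile_image(np.zeros((40, 50)), spec)
        assert pad == (24, 14)
        assert tiles[0].shape == (64, 64)

    def test_tiles_cover_every_pixel(self, rng):
        spec = TileSpec(window=(32, 48), step=(20, 30))
        for _ in range(10):
            shape = (int(rng.integers(10, 90)), int(rng.integers(10, 90)))
            tiles, origins, pad = tile_image(np.zeros(shape), spec)
            cover = np.zeros((shape[0] + pad[0], shape[1] + pad[1]), dtype=int)
            for r, c in origins:
                cover[r : r + 32, c : c + 48] += 1
            assert (cover >= 1).all()

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            TileSpec(window=(32, 32), step=(0, 16))
        with pytest.raises(ValueError):
            TileSpec(window=(32, 32), step=(40, 16))


class TestStitch:
    def test_constant_tiles_give_constant_map(self):
        spec = TileSpec(window=(32, 32), step=(16, 16))
        tiles, origins, pad = tile_image(np.zeros((64, 80)), spec)
        preds = [np.full((32, 32), 0.7) for _ in tiles]
        out = stitch(preds, origins, (64, 80), pad)
        assert out.shape == (64, 80)
        assert np.allclose(out, 0.7)

    def test_two_overlapping_tiles_average(self):
        out = stitch(
            [np.full((4, 4), 0.2), np.full((4, 4), 0.6)],
            [(0, 0), (0, 2)],
            (4, 6),
        )
        assert np.allclose(out[:, :2], 0.2)
        assert np.allclose(out[:, 2:4], 0.4)
        assert np.allclose(out[:, 4:], 0.6)

    def test_uncovered_pixel_is_internal_error(self):
        with pytest.raises(RuntimeError):
            stitch([np.ones((2, 2))], [(0, 0)], (4, 4))

    def test_partition_case_equals_concatenation(self):
        spec = TileSpec(window=(16, 16), step=(16, 16))
        img = np.random.default_rng(1).random((32, 32))
        tiles, origins, pad = tile_image(img, spec)
        out = stitch(tiles, origins, img.shape, pad)
        assert np.array_equal(out, img)

    def test_pointwise_model_leaves_no_seams_on_constant_image(self):
        img = np.full((96, 128), 0.4)
        pmap = predict_2d(img, [PointwiseModel()], InferenceConfig(tiles=TileSpec((32, 32), (16, 16))))
        assert np.all(np.abs(pmap.values - pmap.values[0, 0]) < 1e-6)


class TestEnsembles:
    CFG = InferenceConfig(tiles=TileSpec((32, 32), (16, 16)))

    def test_single_fold_equals_stitched_prediction(self):
        img = np.random.default_rng(2).random((48, 64))
        single = predict_2d(img, [PointwiseModel()], self.CFG)
        tiles, origins, pad = tile_image(img, self.CFG.tiles)
        manual = stitch([PointwiseModel().predict(t) for t in tiles], origins, img.shape, pad)
        assert np.allclose(single.values, manual)

    def test_two_constant_folds_average(self):
        img = np.zeros((32, 32))
        pmap = predict_2d(img, [ConstantModel(0.2), ConstantModel(0.6)], self.CFG)
        assert np.allclose(pmap.values, 0.4)
        assert pmap.n_folds == 2

    def test_ensemble_is_bounded_by_members(self, rng):
        img = rng.random((48, 48))
        members = [PointwiseModel(), ConstantModel(0.1), ConstantModel(0.9)]
        maps = [predict_2d(img, [m], self.CFG).values for m in members]
        ens = predict_2d(img, members, self.CFG).values
        assert np.all(ens >= np.min(maps, axis=0) - 1e-12)
        assert np.all(ens <= np.max(maps, axis=0) + 1e-12)

    def test_no_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            predict_2d(np.zeros((32, 32)), [], self.CFG)


class TestVolumes:
    CFG = InferenceConfig(tiles=TileSpec((32, 32), (16, 16)))

    def test_constant_model_gives_constant_volume(self):
        vol = ImageVolume(np.random.default_rng(0).random((8, 32, 32)))
        pmap = predict_volume(vol, [ConstantModel(0.5)], self.CFG)
        assert pmap.shape == vol.shape
        assert np.allclose(pmap.values, 0.5)
        assert pmap.planes == ("coronal", "sagittal")

    def test_single_plane_reduces_to_slicewise_2d(self):
        vol = np.random.default_rng(1).random((6, 40, 40))
        cfg = InferenceConfig(tiles=self.CFG.tiles, planes=("coronal",))
        pmap = predict_volume(vol, [PointwiseModel()], cfg)
        for j in range(vol.shape[1]):
            expect = predict_2d(vol[:, j, :], [PointwiseModel()], self.CFG).values
            assert np.allclose(pmap.values[:, j, :], expect)

    def test_two_plane_map_is_mean_of_single_plane_maps(self):
        vol = np.random.default_rng(2).random((6, 40, 40))
        both = predict_volume(vol, [PointwiseModel()], InferenceConfig(tiles=self.CFG.tiles))
        cor = predict_volume(vol, [PointwiseModel()], InferenceConfig(tiles=self.CFG.tiles, planes=("coronal",)))
        sag = predict_volume(vol, [PointwiseModel()], InferenceConfig(tiles=self.CFG.tiles, planes=("sagittal",)))
        assert np.allclose(both.values, (cor.values + sag.values) / 2, atol=1e-9)


class TestThreshold:
    def test_just_below_threshold_is_empty(self):
        mask = threshold_probability(np.full((8, 8), 0.79), 0.8)
        assert mask.values.sum() == 0

    def test_at_threshold_is_full_inclusive_rule(self):
        mask = threshold_probability(np.full((8, 8), 0.80), 0.8)
        assert mask.values.all()

    def test_masks_nest_as_threshold_rises(self, rng):
        pmap = rng.random((32, 32))
        prev = threshold_probability(pmap, 0.2).values
        for t in (0.4, 0.6, 0.8):
            cur = threshold_probability(pmap, t).values
            assert not (cur & ~prev).any()  # cur is a subset of prev
            prev = cur

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            threshold_probability(np.zeros((4, 4)), 0.0)
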