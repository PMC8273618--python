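import numpy as np
import pytest

from ccmorph import imgio
from ccmorph.model import ModelConfig
from ccmorph.phantom import PhantomSpec, generate_phantom_2d
from ccmorph.training import (
    AugmentationConfig,
    SampleRecord,
    TrainConfig,
    augment_pair,
    split_by_subject,
    train_cv,
)


def make_records(subjects, samples_per_subject=1):
    recs = []
    for s in subjects:
        for i in range(samples_per_subject):
            recs.append(SampleRecord(f"{s}_img{i}", s, f"/x/{s}_{i}.png", f"/x/{s}_{i}_m.png"))
    return recs


class TestSubjectSplit:
    def test_four_subjects_four_folds_pigeonhole(self):
        folds = split_by_subject(make_records(list("abcd")), 4, seed=0)
        assert sorted(folds.subject_fold.values()) == [0, 1, 2, 3]

    def test_twelve_subjects_round_robin_balance(self):
        folds = split_by_subject(make_records([f"s{i}" for i in range(12)]), 4, seed=5)
        sizes = [len(folds.subjects_in_fold(k)) for k in range(4)]
        assert sizes == [3, 3, 3, 3]

    def test_no_subject_in_two_folds(self):
        recs = make_records([f"s{i}" for i in range(7)], samples_per_subject=3)
        folds = split_by_subject(recs, 3, seed=1)
        for k in range(3):
            val = folds.subjects_in_fold(k)
            train = {r.subject_id for r in recs} - val
            assert not val & train

    def test_deterministic_given_seed(self):
        recs = make_records([f"s{i}" for i in range(9)])
        a = split_by_subject(recs, 4, seed=11)
        b = split_by_subject(recs, 4, seed=11)
        c = split_by_subject(recs, 4, seed=12)
        assert a.subject_fold == b.subject_fold
        assert a.subject_fold != c.subject_fold

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(make_records(["a", "b"]), 4, seed=0)


class TestAugmentation:
    def setup_method(self):
        sample = generate_phantom_2d(PhantomSpec(shape=(64, 64), base_thickness_px=12, seed=2))
        self.img = sample.image.intensities
        self.msk = sample.truth_mask.values

    def test_disabled_config_is_identity(self):
        img, msk = augment_pair(self.img, self.msk, AugmentationConfig.disabled(), seed=0)
        assert np.array_equal(img, self.img)
        assert np.array_equal(msk, self.msk)

    def test_horizontal_flip_is_an_involution(self):
        cfg = AugmentationConfig(hflip_p=1.0, vflip_p=0.0, rotation_deg=0.0,
                                 scale_range=(1.0, 1.0), brightness_range=(0.0, 0.0),
                                 contrast_range=(1.0, 1.0), gamma_range=(1.0, 1.0),
                                 noise_sd_range=(0.0, 0.0))
        i1, m1 = augment_pair(self.img, self.msk, cfg, seed=0)
        i2, m2 = augment_pair(i1, m1, cfg, seed=0)
        assert np.array_equal(i2, self.img)
        assert np.array_equal(m2, self.msk)

    def test_right_angle_rotation_is_lossless(self):
        from ccmorph.training import _rotate_pair

        i90, m90 = _rotate_pair(self.img, self.msk, 90.0, order=1)
        iback, mback = _rotate_pair(i90, m90, -90.0, order=1)
        assert np.array_equal(mback, self.msk)
        assert np.allclose(iback, self.img)

    def test_mask_stays_binary_under_arbitrary_rotation_and_scale(self):
        cfg = AugmentationConfig(rotation_deg=15.0, scale_range=(0.9, 1.1))
        for seed in range(5):
            img, msk = augment_pair(self.img, self.msk, cfg, seed=seed)
            assert msk.dtype == bool
            assert img.shape == self.img.shape == msk.shape
            assert img.min() >= 0 and img.max() <= 1

    def test_photometric_changes_touch_image_only(self):
        cfg = AugmentationConfig(hflip_p=0.0, vflip_p=0.0, rotation_deg=0.0,
                                 scale_range=(1.0, 1.0), brightness_range=(0.1, 0.1),
                                 contrast_range=(1.0, 1.0), gamma_range=(1.0, 1.0),
                                 noise_sd_range=(0.0, 0.0))
        img, msk = augment_pair(self.img, self.msk, cfg, seed=0)
        assert np.array_equal(msk, self.msk)
        assert not np.array_equal(img, self.img)


def _phantom_dataset(tmp_path, n_subjects, seed0=100, shape=(64, 96)):
    recs = []
    for i in range(n_subjects):
        sample = generate_phantom_2d(PhantomSpec(shape=shape, base_thickness_px=14, seed=seed0 + i))
        ip, mp = tmp_path / f"s{i}.png", tmp_path / f"s{i}_m.png"
        imgio.write_image(sample.image, ip, bits=16)
        imgio.write_mask(sample.truth_mask, mp)
        recs.append(SampleRecord(f"s{i}", f"subj{i}", str(ip), str(mp)))
    return recs


TINY_TRAIN = dict(
    n_folds=2,
    epochs=1,
    batch_size=2,
    crops_per_image=1,
    tile_shape=(32, 32),
    augmentation=AugmentationConfig.disabled(),
)


class TestTrainCV:
    def test_one_epoch_run_returns_fold_handles_and_report(self, tmp_path):
        recs = _phantom_dataset(tmp_path, 4)
        cfg = TrainConfig(**TINY_TRAIN, model=ModelConfig(base_channels=4), seed=0)
        folds = split_by_subject(recs, cfg.n_folds, 0)
        models, report = train_cv(recs, folds, cfg, tmp_path / "ckpt")
        assert set(models) == {0, 1}
        assert set(report["fold_dice"]) == {0, 1}
        assert all(len(curve) == 1 for curve in report["loss_curves"].values())
        assert (tmp_path / "ckpt" / "fold0.ckpt").exists()
        assert (tmp_path / "ckpt" / "cv_report.json").exists()

    def test_identical_seed_reproduces_losses_exactly(self, tmp_path):
        recs = _phantom_dataset(tmp_path, 4)
        cfg = TrainConfig(**TINY_TRAIN, model=ModelConfig(base_channels=4), seed=3)
        folds = split_by_subject(recs, cfg.n_folds, 3)
        _, rep1 = train_cv(recs, folds, cfg)
        _, rep2 = train_cv(recs, folds, cfg)
        assert rep1["loss_curves"] == rep2["loss_curves"]
        assert rep1["fold_dice"] == rep2["fold_dice"]

    def test_grouped_leakage_invariant_over_random_draws(self, rng):
        for _ in range(200):
            n_subj = int(rng.integers(4, 16))
            n_folds = int(rng.integers(2, min(n_subj, 6) + 1))
            recs = make_records([f"s{i}" for i in range(n_subj)], samples_per_subject=2)
            folds = split_by_subject(recs, n_folds, int(rng.integers(0, 2**31)))
            for k in range(n_folds):
                val = folds.subjects_in_fold(k)
                train = {r.subject_id for r in recs if folds.fold_of(r.subject_id) != k}
                assert not val & train
                assert val  # every fold non-empty when subjects >= folds
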