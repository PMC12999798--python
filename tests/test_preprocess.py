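"""SUVR, group GM mask, voxel-mean profile and SRP computations."""

import numpy as np
import pytest

from fdgpet import preprocess
from fdgpet.io import Mask, Volume, read_volume
from fdgpet.preprocess import (GMMask, PreprocessConfig, VoxelMeanProfile,
                               build_group_gm_mask, compute_srp, compute_suvr,
                               fit_voxel_mean_profile, preprocess_cohort)


def vol(data):
    return Volume(np.asarray(data, dtype=np.float32))


def mask(data):
    return Mask(np.asarray(data, dtype=bool))


def full_mask(shape):
    return mask(np.ones(shape, dtype=bool))


class TestSUVR:
    def test_constant_pet_gives_unit_suvr_inside_brain(self):
        pet = vol(np.full((4, 4, 4), 5.0))
        brain = mask(np.zeros((4, 4, 4), bool))
        brain.data[1:3, 1:3, 1:3] = True
        ref = mask(np.zeros((4, 4, 4), bool))
        ref.data[1, 1, 1] = True
        suvr = compute_suvr(pet, ref, brain)
        assert np.allclose(suvr.data[brain.data], 1.0)
        assert np.all(suvr.data[~brain.data] == 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        pet = rng.random((5, 5, 5)).astype(np.float32) + 0.5
        ref = mask(rng.random((5, 5, 5)) > 0.6)
        brain = full_mask((5, 5, 5))
        a = compute_suvr(vol(pet), ref, brain)
        b = compute_suvr(vol(pet * 2.0), ref, brain)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-6)

    def test_hand_arithmetic_on_3cube(self):
        pet = np.zeros((3, 3, 3), dtype=np.float32)
        pet[0, 0, 0], pet[0, 0, 1] = 2.0, 4.0   # reference voxels, mean 3
        pet[1, 1, 1] = 6.0
        ref = mask(np.zeros((3, 3, 3), bool))
        ref.data[0, 0, 0] = ref.data[0, 0, 1] = True
        suvr = compute_suvr(vol(pet), ref, full_mask((3, 3, 3)))
        assert suvr.data[1, 1, 1] == pytest.approx(2.0)

    def test_empty_or_nonpositive_reference_rejected(self):
        pet = vol(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            compute_suvr(pet, mask(np.zeros((3, 3, 3))), full_mask((3, 3, 3)))
        ref = mask(np.zeros((3, 3, 3), bool))
        ref.data[0, 0, 0] = True
        zero = vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="reference"):
            compute_suvr(zero, ref, full_mask((3, 3, 3)))


class TestGroupGMMask:
    def test_all_ones_single_map_covers_grid(self):
        gm = build_group_gm_mask([vol(np.ones((4, 4, 4)))],
                                 [mask(np.zeros((4, 4, 4)))], 0.30)
        assert gm.data.all() and gm.n_subjects == 1

    def test_threshold_excludes_voxel_just_below_30_percent(self):
        data = np.ones((3, 3, 3), dtype=np.float32)
        data[0, 0, 0] = 0.29
        data[0, 0, 1] = 0.31
        gm = build_group_gm_mask([vol(data)], [mask(np.zeros((3, 3, 3)))], 0.30)
        assert not gm.data[0, 0, 0]
        assert gm.data[0, 0, 1]

    def test_striatal_indicator_raises_gm_probability(self):
        """A voxel with zero GM probability but inside a striatal mask
        counts as 1 for that subject before averaging."""
        gm1 = np.ones((3, 3, 3), dtype=np.float32)
        gm2 = np.ones((3, 3, 3), dtype=np.float32)
        gm2[1, 1, 1] = 0.0
        striatum = np.zeros((3, 3, 3), bool)
        striatum[1, 1, 1] = True
        with_striatum = build_group_gm_mask(
            [vol(gm1), vol(gm2)], [mask(np.zeros((3, 3, 3))), mask(striatum)],
            0.90)
        without = build_group_gm_mask(
            [vol(gm1), vol(gm2)], [mask(np.zeros((3, 3, 3)))] * 2, 0.90)
        assert with_striatum.data[1, 1, 1]
        assert not without.data[1, 1, 1]

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(2)
        maps = [vol(rng.random((5, 5, 5))) for _ in range(3)]
        empty = [mask(np.zeros((5, 5, 5)))] * 3
        prev = build_group_gm_mask(maps, empty, 0.1).data
        for frac in (0.3, 0.5, 0.7, 0.9):
            cur = build_group_gm_mask(maps, empty, frac).data
            assert not (cur & ~prev).any()
            prev = cur

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_group_gm_mask([], [], 0.3)


class TestVoxelMeanProfileAndSRP:
    def test_identical_subjects_profile_equals_centered_field(self):
        rng = np.random.default_rng(3)
        suvr = vol(rng.random((4, 4, 4)) + 0.5)
        gm = GMMask(full_mask((4, 4, 4)), 0.3, 2)
        brain = full_mask((4, 4, 4))
        profile = fit_voxel_mean_profile([suvr, suvr], gm, brain)
        logs = np.log(suvr.data.astype(np.float64))
        centered = logs - logs.mean()
        np.testing.assert_allclose(profile.data, centered, atol=1e-6)

    def test_global_rescalings_collapse_to_one_profile(self):
        rng = np.random.default_rng(4)
        base = rng.random((4, 4, 4)).astype(np.float32) + 0.5
        cohort = [vol(base), vol(base * 2), vol(base * 0.5)]
        gm = GMMask(full_mask((4, 4, 4)), 0.3, 3)
        profile = fit_voxel_mean_profile(cohort, gm, full_mask((4, 4, 4)))
        logs = np.log(base.astype(np.float64))
        np.testing.assert_allclose(profile.data, logs - logs.mean(), atol=1e-6)

    def test_three_subject_two_voxel_hand_oracle(self):
        # grid of 2 voxels; brain mask = gm mask = both voxels
        fields = [np.array([1.0, 2.0]), np.array([2.0, 2.0]),
                  np.array([1.0, 4.0])]
        subj = [vol(f.reshape(2, 1, 1)) for f in fields]
        gm = GMMask(full_mask((2, 1, 1)), 0.3, 3)
        profile = fit_voxel_mean_profile(subj, gm, full_mask((2, 1, 1)))
        centered = [np.log(f) - np.log(f).mean() for f in fields]
        expected = np.mean(centered, axis=0)
        np.testing.assert_allclose(profile.data[:, 0, 0], expected, atol=1e-6)

    def test_srp_self_centering_is_zero(self):
        rng = np.random.default_rng(5)
        suvr = vol(rng.random((4, 4, 4)) + 0.5)
        gm = GMMask(full_mask((4, 4, 4)), 0.3, 2)
        brain = full_mask((4, 4, 4))
        profile = fit_voxel_mean_profile([suvr, suvr], gm, brain)
        srp = compute_srp(suvr, gm, brain, profile)
        np.testing.assert_allclose(srp.data, 0.0, atol=1e-6)
        doubled = vol(suvr.data * 2)
        srp2 = compute_srp(doubled, gm, brain, profile)
        np.testing.assert_allclose(srp2.data, 0.0, atol=1e-6)

    def test_two_voxel_log_centering_hand_oracle(self):
        suvr = vol(np.array([np.e, np.e ** 3]).reshape(2, 1, 1))
        gm = GMMask(full_mask((2, 1, 1)), 0.3, 2)
        zero_profile = VoxelMeanProfile(
            vol(np.zeros((2, 1, 1))), n_subjects=2)
        srp = compute_srp(suvr, gm, full_mask((2, 1, 1)), zero_profile)
        np.testing.assert_allclose(srp.data[:, 0, 0], [-1.0, 1.0], atol=1e-6)

    def test_linear_center_scale_mode(self):
        suvr = vol(np.array([1.0, 3.0]).reshape(2, 1, 1))
        gm = GMMask(full_mask((2, 1, 1)), 0.3, 2)
        zero_profile = VoxelMeanProfile(vol(np.zeros((2, 1, 1))), 2)
        srp = compute_srp(suvr, gm, full_mask((2, 1, 1)), zero_profile,
                          center_scale="linear")
        np.testing.assert_allclose(srp.data[:, 0, 0], [-1.0, 1.0], atol=1e-6)

    def test_suvr_and_srp_invariant_to_global_pet_rescaling(self, small_cohort):
        """Per-subject global intensity scale must cancel end to end."""
        row = next(small_cohort["manifest"].rows())
        atlas = small_cohort["atlas"]
        pet = read_volume(row.pet_path)
        ref = Mask(atlas.mask_for("cerebellar_gm"), atlas.spacing)
        brain = Mask(atlas.brain_mask.data, atlas.spacing)
        a = compute_suvr(pet, ref, brain)
        b = compute_suvr(Volume(pet.data * 3.7, pet.spacing), ref, brain)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-5)


class TestPreprocessCohort:
    def test_reference_mean_is_one_for_every_subject(self, small_cohort):
        atlas = small_cohort["atlas"]
        ref = atlas.mask_for("cerebellar_gm")
        for row in small_cohort["manifest"].rows():
            suvr = read_volume(row.suvr_path).data
            assert abs(suvr[ref].mean() - 1.0) < 1e-5

    def test_training_srp_mean_is_zero_on_gm_mask(self, small_cohort):
        from fdgpet.io import read_mask
        gm = read_mask(small_cohort["root"] / "prep" / "gm_mask.nii.gz")
        train_rows = small_cohort["manifest"].subset(split="train")
        acc = np.zeros(gm.shape, dtype=np.float64)
        for row in train_rows.rows():
            acc += read_volume(row.srp_path).data
        mean = acc / len(train_rows)
        assert np.abs(mean[gm.data]).max() < 1e-5

    def test_profile_uses_training_subjects_only(self, small_cohort):
        manifest, atlas = small_cohort["manifest"], small_cohort["atlas"]
        stored = read_volume(small_cohort["root"] / "prep" /
                             "voxel_mean_profile.nii.gz")
        from fdgpet.io import read_mask
        gm = GMMask(read_mask(small_cohort["root"] / "prep" / "gm_mask.nii.gz"),
                    0.3, -1)
        ref = Mask(atlas.mask_for("cerebellar_gm"), atlas.spacing)

        def profile_for(split_filter):
            suvrs, brains = [], []
            for row in manifest.rows():
                if split_filter(row.split):
                    pet = read_volume(row.pet_path)
                    brain = Mask(read_volume(row.brain_mask_path).data > 0.5,
                                 atlas.spacing)
                    suvrs.append(compute_suvr(pet, ref, brain))
                    brains.append(brain)
            return fit_voxel_mean_profile(suvrs, gm, brains).data

        train_only = profile_for(lambda s: s == "train")
        everyone = profile_for(lambda s: True)
        np.testing.assert_allclose(stored.data, train_only, atol=1e-6)
        assert np.abs(train_only - everyone).max() > 1e-6

    def test_rerun_is_byte_identical(self, small_cohort, tmp_path):
        manifest = small_cohort["manifest"]
        cohort_dir = small_cohort["root"] / "cohort"
        outs = []
        for name in ("r1", "r2"):
            cfg = PreprocessConfig(out_dir=str(tmp_path / name),
                                   atlas_dir=str(cohort_dir))
            preprocess_cohort(manifest, cfg)
            outs.append(tmp_path / name)
        for f in sorted(p.name for p in outs[0].iterdir() if p.suffix != ".csv"):
            assert (outs[0] / f).read_bytes() == (outs[1] / f).read_bytes(), f

    def test_empty_training_split_rejected(self, small_cohort):
        manifest = small_cohort["manifest"]
        broken = manifest.with_column("split", ["test"] * len(manifest))
        cfg = PreprocessConfig(out_dir="/tmp/unused",
                               atlas_dir=str(small_cohort["root"] / "cohort"))
        with pytest.raises(ValueError, match="training split"):
            preprocess_cohort(broken, cfg)
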