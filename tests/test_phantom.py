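"""Phantom atlas, class signatures, and cohort simulation."""

import numpy as np
import pytest

from fdgpet import phantom
from fdgpet.io import CLASSES, load_manifest, read_volume


class TestAtlas:
    def test_deterministic_and_complete_on_32_cube(self):
        a1 = phantom.make_atlas((32, 32, 32), seed=1)
        a2 = phantom.make_atlas((32, 32, 32), seed=1)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        assert a1.names() == set(phantom.REGION_VOCABULARY)

    def test_every_region_has_at_least_27_voxels(self):
        atlas = phantom.make_atlas((96, 112, 96), seed=7)
        for name in phantom.REGION_VOCABULARY:
            assert atlas.mask_for(name).sum() >= 27, name
        assert atlas.mask_for("cerebellar_gm").sum() >= 27

    def test_regions_disjoint_and_inside_brain(self):
        atlas = phantom.make_atlas((32, 32, 32), seed=3)
        # disjoint by construction of the label volume; named (non-background)
        # regions must lie inside the brain mask
        for name in phantom.REGION_VOCABULARY:
            if name == "background_gm":
                continue
            assert not (atlas.mask_for(name) & ~atlas.brain_mask.data).any(), name

    def test_paired_structures_have_left_and_right_instances(self):
        atlas = phantom.make_atlas((32, 32, 32), seed=0)
        mid = atlas.shape[0] / 2
        for name in phantom.PAIRED_REGIONS:
            mask = atlas.mask_for(name)
            xs = np.nonzero(mask)[0]
            assert (xs < mid).any() and (xs >= mid).any(), name

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            phantom.make_atlas((8, 32, 32), seed=0)

    def test_save_load_round_trip(self, tmp_path):
        atlas = phantom.make_atlas((32, 32, 32), seed=5)
        atlas.save(tmp_path)
        back = phantom.PhantomAtlas.load(tmp_path)
        np.testing.assert_array_equal(back.labels, atlas.labels)
        assert back.region_table == atlas.region_table


class TestSignatures:
    def test_hc_is_identity_and_effect_bounds(self):
        sigs = phantom.default_signatures(1.0)
        assert all(f == 1.0 for f in sigs["HC"].factors.values())
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                phantom.default_signatures(bad)

    def test_qualitative_pattern(self):
        sigs = phantom.default_signatures(1.0)
        for cls in ("AD", "DLB", "Mixed"):
            s = sigs[cls]
            assert s["motor_cortex"] > 1 and s["pallidum"] > 1
            assert s["cerebellar_gm"] > 1
            assert s["parietal"] < 1 and s["lateral_temporal"] < 1
        assert sigs["DLB"]["occipital"] < 1 and sigs["Mixed"]["occipital"] < 1
        assert sigs["AD"]["hippocampus"] < 1 and sigs["Mixed"]["hippocampus"] < 1
        # DLB occipital deficit deeper than AD's (AD has none)
        assert sigs["DLB"]["occipital"] < sigs["AD"]["occipital"]

    def test_mixed_factors_between_or_equal_to_extremes(self):
        sigs = phantom.default_signatures(0.8)
        for name in phantom.REGION_VOCABULARY:
            lo = min(sigs["AD"][name], sigs["DLB"][name])
            hi = max(sigs["AD"][name], sigs["DLB"][name])
            assert lo - 1e-12 <= sigs["Mixed"][name] <= hi + 1e-12, name

    @pytest.mark.parametrize("cls", ["AD", "DLB", "Mixed"])
    def test_effect_monotonicity(self, cls):
        """|factor - 1| strictly increases with effect for affected regions."""
        lo, hi = phantom.default_signatures(0.3), phantom.default_signatures(0.9)
        affected = [n for n, f in phantom.default_signatures(1.0)[cls].factors.items()
                    if abs(f - 1) > 1e-12]
        assert affected
        for name in affected:
            assert abs(hi[cls][name] - 1) > abs(lo[cls][name] - 1), name

    def test_small_effect_approaches_identity(self):
        sigs = phantom.default_signatures(1e-6)
        for cls in CLASSES:
            assert all(abs(f - 1) < 1e-5 for f in sigs[cls].factors.values())


@pytest.fixture(scope="module")
def atlas():
    return phantom.make_atlas((32, 32, 32), seed=2)


class TestSimulateSubject:
    def test_noise_free_hc_equals_baseline(self, atlas):
        params = phantom.PhantomParams(noise_sd=0.0, global_scale_range=(1, 1),
                                       seed=2)
        sig = phantom.default_signatures(0.7)["HC"]
        pet, gm, mask = phantom.simulate_subject("HC", atlas, sig, params, 0)
        np.testing.assert_allclose(pet.data, phantom.baseline_field(atlas),
                                   atol=1e-5)

    def test_deterministic_for_subject_seed(self, atlas):
        params = phantom.PhantomParams(seed=3)
        sig = phantom.default_signatures(0.7)["AD"]
        a = phantom.simulate_subject("AD", atlas, sig, params, 42)
        b = phantom.simulate_subject("AD", atlas, sig, params, 42)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_ad_parietal_below_matched_hc(self, atlas):
        params = phantom.PhantomParams(noise_sd=0.0, global_scale_range=(1, 1),
                                       seed=2)
        sigs = phantom.default_signatures(1.0)
        ad, _, _ = phantom.simulate_subject("AD", atlas, sigs["AD"], params, 5)
        hc, _, _ = phantom.simulate_subject("HC", atlas, sigs["HC"], params, 5)
        par = atlas.mask_for("parietal")
        assert ad.data[par].mean() < hc.data[par].mean()

    def test_missing_signature_region_rejected(self, atlas):
        params = phantom.PhantomParams(seed=2)
        incomplete = phantom.ClassSignature({"occipital": 1.0})
        with pytest.raises(KeyError, match="missing region"):
            phantom.simulate_subject("HC", atlas, incomplete, params, 0)

    def test_gm_probability_ranges(self, atlas):
        params = phantom.PhantomParams(seed=2)
        sig = phantom.default_signatures(0.7)["HC"]
        _, gm, _ = phantom.simulate_subject("HC", atlas, sig, params, 1)
        gm_regions = ~atlas.mask_for("white_matter") & atlas.brain_mask.data
        assert gm.data[gm_regions].min() >= 0.9
        wm = atlas.mask_for("white_matter")
        assert gm.data[wm].max() <= 0.05
        assert gm.data[~atlas.brain_mask.data].max() <= 0.05


class TestSimulateCohort:
    def test_split_is_70_10_20_per_class(self, small_cohort):
        table = small_cohort["manifest"].table
        for cls in CLASSES:
            sub = table[table["label"] == cls]
            counts = sub["split"].value_counts()
            assert (counts["train"], counts["val"], counts["test"]) == (7, 1, 2)

    def test_zero_count_class_absent_and_totals_conserved(self, tmp_path):
        params = phantom.PhantomParams(seed=4)
        manifest, _ = phantom.simulate_cohort({"AD": 3, "DLB": 0, "HC": 3},
                                              params, tmp_path / "c")
        assert len(manifest) == 6
        assert not (manifest.table["label"] == "DLB").any()

    def test_cohort_is_deterministic(self, tmp_path):
        params = phantom.PhantomParams(seed=9)
        m1, _ = phantom.simulate_cohort({"AD": 3, "HC": 3}, params, tmp_path / "a")
        m2, _ = phantom.simulate_cohort({"AD": 3, "HC": 3}, params, tmp_path / "b")
        assert list(m1.table["split"]) == list(m2.table["split"])
        v1 = read_volume(m1.table["pet_path"][0]).data
        v2 = read_volume(m2.table["pet_path"][0]).data
        np.testing.assert_array_equal(v1, v2)

    def test_output_collision_requires_overwrite(self, tmp_path):
        params = phantom.PhantomParams(seed=4)
        phantom.simulate_cohort({"AD": 3, "HC": 3}, params, tmp_path / "c")
        with pytest.raises(FileExistsError):
            phantom.simulate_cohort({"AD": 3, "HC": 3}, params, tmp_path / "c")
        phantom.simulate_cohort({"AD": 3, "HC": 3}, params, tmp_path / "c",
                                overwrite=True)

    def test_manifest_reloads_cleanly(self, small_cohort):
        path = small_cohort["root"] / "cohort" / "manifest.csv"
        back = load_manifest(path)
        assert len(back) == len(small_cohort["manifest"])


def test_class_separability_sign_test(study_cohort):
    """At the study conditions, mean regional SUVR differs between classes
    in the signature's direction for every affected region (sign test on
    per-subject regional means)."""
    from scipy.stats import binomtest

    manifest = study_cohort["manifest"]
    atlas = study_cohort["atlas"]
    sigs = phantom.default_signatures(study_cohort["params"].effect)
    regional = {}
    for row in manifest.rows():
        suvr = read_volume(row.suvr_path).data
        regional.setdefault(row.label, []).append(
            {n: suvr[atlas.mask_for(n)].mean()
             for n in phantom.REGION_VOCABULARY})
    for cls in ("AD", "DLB", "Mixed"):
        for name in phantom.suvr_signal_regions(sigs[cls]):
            expected_sign = np.sign(sigs[cls][name] / sigs[cls]["cerebellar_gm"] - 1)
            diffs = [a[name] - h[name]
                     for a, h in zip(regional[cls], regional["HC"])]
            wins = sum(1 for d in diffs[:20] if np.sign(d) == expected_sign)
            assert binomtest(wins, min(len(diffs), 20), 0.5,
                             alternative="greater").pvalue < 0.01, (cls, name)
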