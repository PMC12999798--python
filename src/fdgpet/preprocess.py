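"""SUVR and SRP computation with persistable training-set statistics.

SUVR: each PET volume is divided by its mean intensity over the cerebellar
gray-matter reference region, then zeroed outside the subject's brain
mask.  No smoothing is applied anywhere in the pipeline.

SRP (subject residual profile): log-SUVR doubly centered — subtract each
subject's whole-brain mean of log-SUVR, then subtract the per-voxel mean
of those subject-centered fields over the training cohort, restricted to
the study-specific gray-matter mask.  The subject-centering support is the
brain mask, the voxel-centering support the GM mask.  Centering on the log
scale follows the scaled-subprofile-model convention; a ``linear`` mode is
exposed for comparison but log/log is the tested canonical path.

The study-specific GM mask is built from training subjects only: each
subject's GM probability map is merged with a striatal indicator by
voxelwise maximum, the merged maps are averaged, and voxels below a
fraction (default 30%) of the averaged map's maximum are excluded.  For
out-of-sample subjects the persisted training-set voxel-mean profile is
reused unchanged; this mirrors the inherent imperfection of centering test
data with training statistics rather than attempting to fix it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (CohortManifest, Mask, Volume, read_mask, read_volume,
                 save_manifest, write_mask, write_volume)
from .phantom import PhantomAtlas

logger = logging.getLogger(__name__)

SUVR_FLOOR = 1e-6  # floor for nonpositive SUVR inside the mask before log


@dataclass
class GMMask:
    """Study-specific gray-matter mask with provenance."""

    mask: Mask
    threshold_frac: float
    n_subjects: int

    @property
    def data(self) -> np.ndarray:
        return self.mask.data


@dataclass
class VoxelMeanProfile:
    """Per-voxel mean of subject-centered log-SUVR over a training cohort.

    Zero outside the GM mask.
    """

    volume: Volume
    n_subjects: int

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def compute_suvr(pet: Volume, reference_mask: Mask, brain_mask: Mask) -> Volume:
    """PET / mean(PET over cerebellar reference), zeroed outside the brain."""
    if not pet.same_grid(reference_mask) or not pet.same_grid(brain_mask):
        raise ValueError("pet, reference_mask and brain_mask must share one grid")
    ref = reference_mask.data
    if not ref.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(pet.data[ref].mean())
    if ref_mean <= 0:
        raise ValueError(f"nonpositive reference-region mean: {ref_mean}")
    suvr = pet.data / ref_mean
    suvr = np.where(brain_mask.data, suvr, 0.0)
    return Volume(suvr.astype(np.float32), pet.spacing, pet.space_tag)


def build_group_gm_mask(gm_prob_maps: list[Volume], striatal_masks: list[Mask],
                        threshold_frac: float = 0.30) -> GMMask:
    """Average striatum-merged GM probability maps and threshold.

    Per subject the GM probability is raised to 1 inside that subject's
    striatal mask (voxelwise maximum); the across-subject average is then
    thresholded at ``threshold_frac`` times its maximum.
    """
    if not gm_prob_maps:
        raise ValueError("empty GM probability map list")
    if len(striatal_masks) != len(gm_prob_maps):
        raise ValueError("need one striatal mask per GM probability map")
    if not 0 < threshold_frac < 1:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    first = gm_prob_maps[0]
    acc = np.zeros(first.shape, dtype=np.float64)
    for gm, st in zip(gm_prob_maps, striatal_masks):
        if not gm.same_grid(first) or not st.same_grid(first):
            raise ValueError("all maps and masks must share one grid")
        acc += np.maximum(gm.data, st.data.astype(np.float32))
    avg = acc / len(gm_prob_maps)
    cutoff = threshold_frac * avg.max()
    mask = avg >= cutoff
    return GMMask(mask=Mask(mask, first.spacing, first.space_tag),
                  threshold_frac=float(threshold_frac),
                  n_subjects=len(gm_prob_maps))


def _centered_log(suvr: Volume, brain_mask: Mask, scale: str) -> np.ndarray:
    """Subject-centered (log-)SUVR field over the brain mask."""
    values = suvr.data.astype(np.float64)
    inside = brain_mask.data
    if scale == "log":
        n_bad = int((values[inside] <= 0).sum())
        if n_bad:
            logger.warning("flooring %d nonpositive SUVR voxel(s) at %g before log",
                           n_bad, SUVR_FLOOR)
        values = np.log(np.maximum(values, SUVR_FLOOR))
    elif scale != "linear":
        raise ValueError(f"center_scale must be 'log' or 'linear', got {scale!r}")
    subject_mean = values[inside].mean()
    return values - subject_mean


def fit_voxel_mean_profile(suvr_set: list[Volume], gm_mask: GMMask,
                           brain_masks: list[Mask] | Mask,
                           center_scale: str = "log") -> VoxelMeanProfile:
    """Fit the per-voxel mean of subject-centered log-SUVR on the GM mask."""
    if len(suvr_set) < 2:
        raise ValueError("need at least 2 subjects to fit a voxel-mean profile")
    if isinstance(brain_masks, Mask):
        brain_masks = [brain_masks] * len(suvr_set)
    if not gm_mask.data.any():
        raise ValueError("empty GM mask")
    acc = np.zeros(suvr_set[0].shape, dtype=np.float64)
    for suvr, bm in zip(suvr_set, brain_masks):
        acc += _centered_log(suvr, bm, center_scale)
    profile = acc / len(suvr_set)
    profile[~gm_mask.data] = 0.0
    vol = Volume(profile, suvr_set[0].spacing, suvr_set[0].space_tag)
    return VoxelMeanProfile(volume=vol, n_subjects=len(suvr_set))


def compute_srp(suvr: Volume, gm_mask: GMMask, brain_mask: Mask,
                profile: VoxelMeanProfile, center_scale: str = "log") -> Volume:
    """Doubly centered (log-)SUVR on the GM mask; zero elsewhere."""
    if not suvr.same_grid(brain_mask) or not suvr.same_grid(profile.volume):
        raise ValueError("suvr, brain_mask and profile must share one grid")
    centered = _centered_log(suvr, brain_mask, center_scale)
    srp = centered - profile.data
    srp[~gm_mask.data] = 0.0
    return Volume(srp, suvr.spacing, suvr.space_tag)


# ---------------------------------------------------------------------------
# Cohort-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Configuration for the cohort preprocessing pass.

    ``atlas_dir`` must point at a saved :class:`PhantomAtlas` (or an
    equivalent label volume directory) supplying the cerebellar reference
    region and the striatal (putamen + caudate) indicator.
    """

    out_dir: str
    atlas_dir: str
    threshold_frac: float = 0.30
    center_scale: str = "log"
    striatal_regions: tuple[str, ...] = ("putamen", "caudate")
    reference_region: str = "cerebellar_gm"


def preprocess_cohort(manifest: CohortManifest,
                      config: PreprocessConfig) -> CohortManifest:
    """Compute SUVR and SRP volumes for every subject in the manifest.

    The group GM mask and voxel-mean profile are fit on training-split
    subjects only and applied unchanged to validation and test subjects.
    Writes ``gm_mask.nii.gz``, ``voxel_mean_profile.nii.gz``, per-subject
    SUVR/SRP volumes and an augmented ``manifest.csv`` into ``out_dir``;
    returns the augmented manifest.
    """
    out_dir = Path(config.out_dir).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas = PhantomAtlas.load(config.atlas_dir)
    reference_mask = Mask(atlas.mask_for(config.reference_region), atlas.spacing)
    striatal = np.zeros(atlas.shape, dtype=bool)
    for name in config.striatal_regions:
        striatal |= atlas.mask_for(name)
    striatal_mask = Mask(striatal, atlas.spacing)

    train = manifest.subset(split="train")
    if len(train) == 0:
        raise ValueError("training split is empty; cannot fit preprocessing stats")

    # per-subject SUVR
    suvr_by_id: dict[str, Volume] = {}
    brain_by_id: dict[str, Mask] = {}
    for row in manifest.rows():
        pet = read_volume(row.pet_path)
        brain = read_mask(row.brain_mask_path)
        if not pet.same_grid(reference_mask):
            raise ValueError(
                f"{row.subject_id}: PET grid {pet.shape} does not match "
                f"atlas grid {reference_mask.shape}")
        suvr_by_id[row.subject_id] = compute_suvr(pet, reference_mask, brain)
        brain_by_id[row.subject_id] = brain

    # training-only statistics
    train_ids = [r.subject_id for r in train.rows()]
    gm_maps = [read_volume(r.gm_prob_path) for r in train.rows()]
    gm_mask = build_group_gm_mask(gm_maps, [striatal_mask] * len(gm_maps),
                                  config.threshold_frac)
    profile = fit_voxel_mean_profile([suvr_by_id[i] for i in train_ids], gm_mask,
                                     [brain_by_id[i] for i in train_ids],
                                     config.center_scale)

    write_mask(gm_mask.mask, out_dir / "gm_mask.nii.gz")
    write_volume(profile.volume, out_dir / "voxel_mean_profile.nii.gz")

    suvr_paths, srp_paths = [], []
    for row in manifest.rows():
        suvr = suvr_by_id[row.subject_id]
        srp = compute_srp(suvr, gm_mask, brain_by_id[row.subject_id], profile,
                          config.center_scale)
        sp = out_dir / f"{row.subject_id}_suvr.nii.gz"
        rp = out_dir / f"{row.subject_id}_srp.nii.gz"
        write_volume(suvr, sp)
        write_volume(srp, rp)
        suvr_paths.append(str(sp))
        srp_paths.append(str(rp))

    augmented = manifest.with_column("suvr_path", suvr_paths)
    augmented = augmented.with_column("srp_path", srp_paths)
    save_manifest(augmented, out_dir / "manifest.csv")
    return augmented


def load_preprocessing_stats(out_dir):
    """Reload the persisted GM mask and voxel-mean profile."""
    out_dir = Path(out_dir)
    mask = read_mask(out_dir / "gm_mask.nii.gz")
    profile = read_volume(out_dir / "voxel_mean_profile.nii.gz")
    return (GMMask(mask=mask, threshold_frac=float("nan"), n_subjects=-1),
            VoxelMeanProfile(volume=profile, n_subjects=-1))
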