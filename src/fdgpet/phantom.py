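"""Synthetic brain phantoms with class-specific metabolic signatures.

Real FDG-PET cohorts for the four diagnostic groups (AD, DLB, Mixed, HC)
are not distributable, so this module builds a deterministic stand-in: a
labeled region "atlas" of blob-shaped structures inside an ellipsoidal
brain, per-class multiplicative regional metabolism factors, and simulated
subjects combining a baseline uptake field, the class signature, a random
per-subject global scale, and additive voxel noise.

The class signatures encode the qualitative pattern reported for these
groups: all three dementia classes show relative hypermetabolism in motor
cortex, pallidum and cerebellum and hypometabolism in parietal and lateral
temporal cortex versus HC; DLB additionally shows the occipital deficit
that is its classic FDG-PET biomarker; AD additionally shows a hippocampal
deficit.  The Mixed class carries the composition of the AD-specific and
DLB-specific deviations on top of the shared pattern, the simplest model
of a brain bearing both pathologies.

The per-subject global scale makes raw intensities non-comparable across
subjects — exactly the nuisance SUVR normalization must remove — and the
additive Gaussian noise is spatially uncorrelated, matching a pipeline
that applies no smoothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (CLASSES, CohortManifest, Mask, Volume, save_manifest,
                 write_mask, write_volume)

# region vocabulary ---------------------------------------------------------

PAIRED_REGIONS = (
    "occipital", "parietal", "lateral_temporal", "motor_cortex", "frontal",
    "hippocampus", "amygdala", "putamen", "pallidum", "caudate",
)
UNPAIRED_REGIONS = ("cerebellar_gm", "white_matter", "background_gm")
REGION_VOCABULARY = PAIRED_REGIONS + UNPAIRED_REGIONS

GM_BASELINE = 100.0  # intensity units in gray matter
WM_BASELINE = 60.0   # intensity units in white matter

# Cortical structures are large sectors of the shell between the brain
# ellipsoid and an inner (white-matter) ellipsoid, split at the left-right
# midline into paired instances — lobe-scale extents matter because the
# class signatures act multiplicatively on whole regions, as lobar
# hypometabolism does.  Subcortical structures are small mirrored spheres
# placed inside the white-matter core (axis 0 = left-right, axis 1 =
# posterior->anterior, axis 2 = inferior->superior; fractions of the grid).
_SUBCORTICAL_CENTERS = {
    "hippocampus": (0.30, 0.40, 0.45),
    "amygdala":    (0.30, 0.58, 0.38),
    "putamen":     (0.28, 0.50, 0.57),
    "pallidum":    (0.38, 0.64, 0.55),
    "caudate":     (0.33, 0.74, 0.46),
}
_CEREBELLUM_CENTER = (0.50, 0.19, 0.28)
_BRAIN_SEMI = (0.44, 0.48, 0.44)
_INNER_SEMI = (0.30, 0.34, 0.30)

MIN_REGION_VOXELS = 27


@dataclass
class PhantomAtlas:
    """Labeled synthetic region atlas.

    ``labels`` holds integer region ids (0 = outside brain);
    ``region_table`` maps id -> region name (paired structures contribute
    two ids, one per hemisphere, sharing a name).
    """

    labels: np.ndarray
    region_table: dict[int, str]
    brain_mask: Mask
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask_for(self, name: str) -> np.ndarray:
        """Boolean mask of all instances of a named region."""
        ids = [i for i, n in self.region_table.items() if n == name]
        if not ids:
            raise KeyError(f"region {name!r} not in atlas")
        return np.isin(self.labels, ids)

    def names(self) -> set[str]:
        return set(self.region_table.values())

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_volume(Volume(self.labels.astype(np.float32), self.spacing),
                     directory / "atlas_labels.nii.gz")
        write_mask(self.brain_mask, directory / "atlas_brain_mask.nii.gz")
        (directory / "atlas_regions.json").write_text(
            json.dumps({str(k): v for k, v in self.region_table.items()},
                       indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "PhantomAtlas":
        from .io import read_mask, read_volume
        directory = Path(directory)
        labels = read_volume(directory / "atlas_labels.nii.gz")
        mask = read_mask(directory / "atlas_brain_mask.nii.gz")
        table = {int(k): v for k, v in json.loads(
            (directory / "atlas_regions.json").read_text()).items()}
        return cls(labels=np.rint(labels.data).astype(np.int32),
                   region_table=table, brain_mask=mask,
                   spacing=labels.spacing)


@dataclass
class ClassSignature:
    """Per-region multiplicative metabolic factors (1.0 = HC baseline)."""

    factors: dict[str, float]

    def __post_init__(self):
        for name, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {name!r} must be positive, got {f}")

    def __getitem__(self, name: str) -> float:
        return self.factors[name]


@dataclass
class PhantomParams:
    """Cohort-level simulation parameters.

    Defaults are the package's study conditions: a 32^3 grid, per-subject
    global scale uniform on [0.8, 1.2], additive Gaussian noise with sd 5
    intensity units (5% of the gray-matter baseline), effect strength 0.7.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    global_scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 5.0
    effect: float = 0.7
    seed: int = 0
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.global_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("global_scale_range must be positive and ordered")


def _ellipsoid(shape, center_frac, semi_frac) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, s, c, a in zip(grids, shape, center_frac, semi_frac):
        acc = acc + ((g - c * (s - 1)) / max(a * s, 1e-9)) ** 2
    return acc <= 1.0


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c in zip(grids, center):
        acc = acc + (g - c) ** 2
    return acc <= radius ** 2


def make_atlas(grid_shape, seed: int = 0,
               spacing=(2.0, 2.0, 2.0)) -> PhantomAtlas:
    """Build the deterministic synthetic atlas for a grid.

    The brain is an ellipsoid whose outer shell (outside an inner
    white-matter ellipsoid) is gray matter; lobe-scale cortical regions
    are sectors of that shell split at the left-right midline into paired
    instances, the cerebellar reference is a posterior-inferior midline
    sphere, and the five subcortical structures are mirrored spheres with
    a small seeded position jitter.  Shell gray matter not claimed by a
    named region becomes ``background_gm``.  Raises if the grid cannot
    host every region with at least 27 voxels.
    """
    shape = tuple(int(s) for s in grid_shape)
    if any(s < 16 for s in shape):
        raise ValueError(f"grid {shape} too small: every dimension must be >= 16")
    min_dim = min(shape)
    rng = np.random.default_rng([int(seed), 0xA71A5])
    r_sub = max(2.0, 0.07 * min_dim)
    r_cb = max(2.5, 0.08 * min_dim)
    jitter_scale = 0.005 * min_dim

    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    # fractional coordinates per axis
    fx = grids[0] / (shape[0] - 1)
    fy = grids[1] / (shape[1] - 1)
    fz = grids[2] / (shape[2] - 1)

    brain = _ellipsoid(shape, (0.5, 0.5, 0.5), _BRAIN_SEMI)
    inner = _ellipsoid(shape, (0.5, 0.5, 0.5), _INNER_SEMI)
    shell = brain & ~inner
    left = np.broadcast_to(fx < 0.5, shape)

    # cortical sectors of the shell (before carving by cerebellum/spheres)
    lateral = np.broadcast_to(np.abs(fx - 0.5) >= 0.26, shape)
    mid_band = (fy >= 0.35) & (fy < 0.65)
    sectors = {
        "occipital": shell & np.broadcast_to(fy < 0.35, shape),
        "parietal": shell & np.broadcast_to(mid_band & (fy < 0.55), shape)
                    & np.broadcast_to(fz >= 0.60, shape),
        "motor_cortex": shell & np.broadcast_to(mid_band & (fy >= 0.55), shape)
                        & np.broadcast_to(fz >= 0.60, shape),
        "frontal": shell & np.broadcast_to(fy >= 0.65, shape),
        "lateral_temporal": shell & np.broadcast_to(mid_band, shape)
                            & np.broadcast_to(fz < 0.45, shape) & lateral,
    }

    labels = np.zeros(shape, dtype=np.int32)
    table: dict[int, str] = {}
    next_id = 1

    def assign(name, mask, carve=True):
        nonlocal next_id
        mask = mask if not carve else (mask & True)
        labels[mask] = next_id
        table[next_id] = name
        next_id += 1

    assign("white_matter", inner)
    for name, sector in sectors.items():
        assign(name, sector & left)
        assign(name, sector & ~left)

    # cerebellum and subcortical spheres carve whatever they overlap
    cb_center = np.array([c * (s - 1) for c, s in zip(_CEREBELLUM_CENTER, shape)])
    cb_center += rng.uniform(-jitter_scale, jitter_scale, size=3)
    assign("cerebellar_gm", _sphere(shape, cb_center, r_cb) & brain)
    for name in ("hippocampus", "amygdala", "putamen", "pallidum", "caudate"):
        cx, cy, cz = _SUBCORTICAL_CENTERS[name]
        jit = rng.uniform(-jitter_scale, jitter_scale, size=3)
        base = np.array([cx * (shape[0] - 1), cy * (shape[1] - 1),
                         cz * (shape[2] - 1)]) + jit
        mirror = base.copy()
        mirror[0] = (shape[0] - 1) - base[0]
        assign(name, _sphere(shape, base, r_sub))
        assign(name, _sphere(shape, mirror, r_sub))

    bg_id = next_id
    table[bg_id] = "background_gm"
    labels[brain & (labels == 0)] = bg_id

    atlas = PhantomAtlas(labels=labels, region_table=table,
                         brain_mask=Mask(brain, spacing), spacing=tuple(spacing))
    for name in REGION_VOCABULARY:
        count = int(atlas.mask_for(name).sum())
        if count < MIN_REGION_VOXELS:
            raise ValueError(
                f"grid {shape} too small to host all regions: "
                f"{name!r} has {count} voxels (< {MIN_REGION_VOXELS})")
    return atlas


# ---------------------------------------------------------------------------
# Class signatures
# ---------------------------------------------------------------------------

# full-effect factors; deviation from 1 scales linearly with `effect`
_SHARED = {"motor_cortex": 1.15, "pallidum": 1.15, "cerebellar_gm": 1.10,
           "parietal": 0.80, "lateral_temporal": 0.82}
_AD_SPECIFIC = {"hippocampus": 0.80}
_DLB_SPECIFIC = {"occipital": 0.78}
# In mixed disease the coexisting pathologies interact and the DLB-typical
# pattern is partially masked, so the Mixed class carries the AD-specific
# deviation in full but only an attenuated occipital deficit — this is what
# makes Mixed mimic AD and remain the hardest class to call.
MIXED_DLB_ATTENUATION = 0.5


def default_signatures(effect: float) -> dict[str, ClassSignature]:
    """Per-class signatures at an effect strength in (0, 1].

    HC is identically 1.  AD/DLB/Mixed share hyper (motor cortex, pallidum,
    cerebellum) and hypo (parietal, lateral temporal) factors; AD and Mixed
    add the hippocampal deficit; DLB and Mixed add the occipital deficit.
    Mixed composes the AD-specific deviation with an attenuated DLB-specific
    deviation, so every Mixed factor lies between (or equals) the AD and DLB
    extremes.
    """
    if not 0 < effect <= 1:
        raise ValueError(f"effect must be in (0, 1], got {effect}")

    def attenuate(part, weight):
        return {name: 1.0 + weight * (f - 1.0) for name, f in part.items()}

    def build(*parts):
        full = {name: 1.0 for name in REGION_VOCABULARY}
        for part in parts:
            for name, f in part.items():
                full[name] *= f
        return ClassSignature(
            {name: 1.0 + effect * (f - 1.0) for name, f in full.items()})

    return {
        "HC": build(),
        "AD": build(_SHARED, _AD_SPECIFIC),
        "DLB": build(_SHARED, _DLB_SPECIFIC),
        "Mixed": build(_SHARED, _AD_SPECIFIC,
                       attenuate(_DLB_SPECIFIC, MIXED_DLB_ATTENUATION)),
    }


# ---------------------------------------------------------------------------
# Subject and cohort simulation
# ---------------------------------------------------------------------------

def suvr_signal_regions(signature: ClassSignature, tol: float = 1e-9) -> list[str]:
    """Regions carrying class signal in SUVR images.

    A region is informative when its factor deviates from baseline; the
    cerebellar reference is excluded because dividing by the reference
    mean pins its own SUVR at 1 regardless of its factor (a hypermetabolic
    reference instead rescales every other region).
    """
    return [name for name, f in signature.factors.items()
            if abs(f - 1.0) > tol and name != "cerebellar_gm"]


def baseline_field(atlas: PhantomAtlas) -> np.ndarray:
    """Noise-free HC uptake: 100 in gray matter, 60 in white matter, 0 outside."""
    base = np.zeros(atlas.shape, dtype=np.float64)
    for rid, name in atlas.region_table.items():
        value = WM_BASELINE if name == "white_matter" else GM_BASELINE
        base[atlas.labels == rid] = value
    return base


def simulate_subject(label: str, atlas: PhantomAtlas, signature: ClassSignature,
                     params: PhantomParams, subject_seed: int):
    """Simulate one subject; returns (pet, gm_prob, brain_mask).

    pet = global_scale * baseline(region) * signature(region) + N(0, noise_sd),
    clipped at zero; gm_prob is ~[0.9, 1] in gray-matter regions and near 0
    in white matter and background.  Fully determined by
    (params, subject_seed).
    """
    if tuple(atlas.shape) != tuple(params.grid_shape):
        raise ValueError(f"atlas grid {atlas.shape} != params grid {params.grid_shape}")
    missing = sorted(atlas.names() - set(signature.factors))
    if missing:
        raise KeyError(f"signature missing region(s) present in the atlas: {missing}")
    rng = np.random.default_rng([int(params.seed), int(subject_seed)])
    gscale = rng.uniform(*params.global_scale_range)

    field = np.zeros(atlas.shape, dtype=np.float64)
    for rid, name in atlas.region_table.items():
        base = WM_BASELINE if name == "white_matter" else GM_BASELINE
        field[atlas.labels == rid] = base * signature[name]
    pet = gscale * field
    if params.noise_sd > 0:
        pet = pet + rng.normal(0.0, params.noise_sd, size=atlas.shape)
    pet = np.clip(pet, 0.0, None)

    gm = np.zeros(atlas.shape, dtype=np.float64)
    gm_region = np.zeros(atlas.shape, dtype=bool)
    for rid, name in atlas.region_table.items():
        if name != "white_matter":
            gm_region |= atlas.labels == rid
    gm[gm_region] = rng.uniform(0.9, 1.0, size=int(gm_region.sum()))
    wm_or_bg = atlas.brain_mask.data & ~gm_region
    gm[wm_or_bg] = rng.uniform(0.0, 0.05, size=int(wm_or_bg.sum()))

    sp = params.spacing
    return (Volume(pet, sp), Volume(gm, sp),
            Mask(atlas.brain_mask.data.copy(), sp))


def simulate_cohort(n_per_class: dict[str, int], params: PhantomParams,
                    out_dir, overwrite: bool = False):
    """Simulate and write a full cohort; returns (manifest, atlas).

    Writes per-subject pet/gm_prob/brain_mask NIfTI files, the atlas, and
    a manifest with a per-class 70/10/20 train/val/test assignment
    (largest-remainder rounding).  Deterministic given params.seed.
    """
    from .train import assign_splits

    out_dir = Path(out_dir).resolve()
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    unknown = sorted(set(n_per_class) - set(CLASSES))
    if unknown:
        raise ValueError(f"unknown class(es): {unknown}")
    if any(n < 0 for n in n_per_class.values()):
        raise ValueError("subject counts must be >= 0")

    atlas = make_atlas(params.grid_shape, seed=params.seed, spacing=params.spacing)
    atlas.save(out_dir)
    signatures = default_signatures(params.effect)

    rows = []
    for ci, cls in enumerate(CLASSES):
        n = int(n_per_class.get(cls, 0))
        for i in range(n):
            subject_seed = ci * 100_000 + i
            sid = f"{cls}_{i:03d}"
            pet, gm, mask = simulate_subject(cls, atlas, signatures[cls],
                                             params, subject_seed)
            pet_p = out_dir / f"{sid}_pet.nii.gz"
            gm_p = out_dir / f"{sid}_gmprob.nii.gz"
            mask_p = out_dir / f"{sid}_brainmask.nii.gz"
            write_volume(pet, pet_p)
            write_volume(gm, gm_p)
            write_mask(mask, mask_p)
            rows.append({"subject_id": sid, "label": cls,
                         "pet_path": str(pet_p), "gm_prob_path": str(gm_p),
                         "brain_mask_path": str(mask_p)})

    import pandas as pd
    df = pd.DataFrame(rows, columns=["subject_id", "label", "pet_path",
                                     "gm_prob_path", "brain_mask_path"])
    df["split"] = assign_splits(df["label"].tolist(), seed=params.seed)
    manifest = CohortManifest(df)
    save_manifest(manifest, out_dir / "manifest.csv")
    (out_dir / "params.json").write_text(json.dumps({
        "grid_shape": list(params.grid_shape),
        "global_scale_range": list(params.global_scale_range),
        "noise_sd": params.noise_sd, "effect": params.effect,
        "seed": params.seed, "spacing": list(params.spacing),
    }, indent=2))
    return manifest, atlas
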