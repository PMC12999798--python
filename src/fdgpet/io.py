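"""Volume, mask and manifest I/O plus model-bundle persistence.

Volumes travel as NIfTI (``.nii``/``.nii.gz``) through :mod:`nibabel`;
cohort manifests are CSV/TSV tables handled with :mod:`pandas`.  All
volumes are stored as 32-bit float (masks as 8-bit 0/1), and every volume
in a run must live on one common grid — grid mismatches are an error, not
a resampling trigger, because the pipeline consumes already-registered
images.

The first voxel axis is the declared left-right axis (used by the flip
augmentation and by laterality reporting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

LR_AXIS = 0  # declared left-right axis; low indices = left

CLASSES = ("AD", "DLB", "Mixed", "HC")
SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ("subject_id", "label", "pet_path", "gm_prob_path",
                    "brain_mask_path", "split")

_CANONICAL_LABELS = {c.lower(): c for c in CLASSES}


@dataclass
class Volume:
    """A 3D scalar field on a regular grid.

    Attributes
    ----------
    data : float32 array, shape (D, H, W)
    spacing : voxel size in mm per axis
    space_tag : "mni_like" for registered clinical-style grids,
        "phantom" for synthetic grids
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = "phantom"

    def __post_init__(self):
        # float64 survives in memory for exact-arithmetic paths; files are
        # always written as 32-bit float
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(
                f"volume contains {n_bad} non-finite voxel{'s' if n_bad != 1 else ''}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class Mask:
    """A boolean volume on the same grid convention as :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = "phantom"

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"Mask data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def _affine_from_spacing(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def read_volume(path) -> Volume:
    """Read a 3D NIfTI file (4D with a singleton last axis is squeezed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    tag = "phantom"
    descrip = img.header.get("descrip")
    if descrip is not None:
        text = np.asarray(descrip).tobytes().decode("utf-8", "ignore").strip("\x00")
        if text in ("mni_like", "phantom"):
            tag = text
    return Volume(data=data.astype(np.float32), spacing=spacing, space_tag=tag)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as 32-bit float NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(volume.data.astype(np.float32),
                          _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = volume.space_tag.encode()
    nib.save(img, str(path))


def read_mask(path) -> Mask:
    v = read_volume(path)
    return Mask(data=v.data > 0.5, spacing=v.spacing, space_tag=v.space_tag)


def write_mask(mask: Mask, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    img.header["descrip"] = mask.space_tag.encode()
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Table of subjects: id, class label, volume paths, split assignment.

    Extra columns (e.g. ``suvr_path``/``srp_path`` added by preprocessing,
    or a ``train_only`` flag for appended external cohorts) are preserved.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in MANIFEST_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing required column(s): {missing}")
        if "split" not in df.columns:
            df["split"] = "unassigned"
        df["split"] = df["split"].fillna("unassigned")
        df["subject_id"] = df["subject_id"].astype(str)
        labels = df["label"].astype(str)
        bad = sorted(set(l for l in labels if l.lower() not in _CANONICAL_LABELS))
        if bad:
            raise ValueError(f"unknown class label(s): {bad}; expected one of {CLASSES}")
        df["label"] = [_CANONICAL_LABELS[l.lower()] for l in labels]
        dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate subject_id(s): {dupes}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def rows(self):
        return self.table.itertuples(index=False)

    def subset(self, *, split=None, labels=None) -> "CohortManifest":
        df = self.table
        if split is not None:
            df = df[df["split"] == split]
        if labels is not None:
            df = df[df["label"].isin(labels)]
        return CohortManifest(df.reset_index(drop=True))

    def with_column(self, name, values) -> "CohortManifest":
        df = self.table.copy()
        df[name] = values
        return CohortManifest(df)


def load_manifest(path, *, check_files: bool = True) -> CohortManifest:
    """Load a CSV/TSV cohort manifest; relative paths resolve against the
    manifest's own directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    manifest = CohortManifest(df)
    root = path.parent
    resolved = manifest.table.copy()
    for col in resolved.columns:
        if col.endswith("_path"):
            resolved[col] = [
                str(root / p) if (p and not Path(p).is_absolute()) else p
                for p in resolved[col].fillna("")
            ]
    manifest = CohortManifest(resolved)
    if check_files:
        for col in ("pet_path", "gm_prob_path", "brain_mask_path"):
            for p in manifest.table[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    return manifest


def save_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    manifest.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained model's portable form: spec dict + flat weight arrays.

    ``spec`` carries everything needed to rebuild the architecture
    (model name, image type(s), class set, grid, channel widths, padding
    choices); ``weights`` is the ordered parameter list of the rebuilt
    module tree.  ``preprocessing_stats`` records the paths of the GM mask
    and voxel-mean profile in force when the model was trained.
    """

    spec: dict
    weights: list
    preprocessing_stats: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)


def save_bundle(bundle: ModelBundle, directory) -> None:
    """Persist a bundle as a directory: spec.json + one .npy per array.

    Plain ``np.save`` files make the round trip byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": bundle.spec,
        "preprocessing_stats": bundle.preprocessing_stats,
        "history": bundle.history,
        "n_arrays": len(bundle.weights),
    }
    (directory / "spec.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for i, arr in enumerate(bundle.weights):
        np.save(directory / f"w{i:04d}.npy", np.asarray(arr, dtype=np.float32))


def load_bundle(directory) -> ModelBundle:
    directory = Path(directory)
    meta_path = directory / "spec.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a model bundle (no spec.json): {directory}")
    meta = json.loads(meta_path.read_text())
    weights = [np.load(directory / f"w{i:04d}.npy")
               for i in range(meta["n_arrays"])]
    return ModelBundle(spec=meta["spec"], weights=weights,
                       preprocessing_stats=meta.get("preprocessing_stats", {}),
                       history=meta.get("history", {}))
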