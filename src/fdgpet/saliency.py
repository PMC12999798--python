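"""Grad-CAM saliency, class-level averaging, and atlas-ROI extraction.

For a binary backbone the Grad-CAM target layer is the last convolutional
feature map before pooling (the context-module output): channel weights
are the spatially averaged gradients of the target-class logit, the map
is the rectified channel-weighted sum, upsampled to the input grid by
trilinear interpolation.  Subject-level maps of correctly classified test
subjects are averaged per class and the class-level map is min-max
normalized to [0, 1]; regions whose saliency exceeds a threshold (default
0.7) are reported with laterality relative to the left-right axis
midline.  The multiclass model is excluded from saliency reporting: its
concatenated multi-extractor features make channel-weighted maps hard to
attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .io import LR_AXIS
from .nets import Backbone
from .phantom import PhantomAtlas

logger = logging.getLogger(__name__)

DEFAULT_ROI_THRESHOLD = 0.7


@dataclass
class SaliencyMap:
    data: np.ndarray           # nonnegative relevance on the input grid
    model_name: str
    class_label: str
    n_subjects: int


@dataclass
class ROIRow:
    region: str
    laterality: str            # "left" | "right" | "bilateral"
    peak: float
    voxel_fraction: float      # fraction of the qualifying side(s) above threshold


def _upsample(cam: np.ndarray, target_shape) -> np.ndarray:
    factors = [t / s for t, s in zip(target_shape, cam.shape)]
    out = zoom(cam, factors, order=1, mode="grid-constant", grid_mode=True)
    if out.shape != tuple(target_shape):  # guard against rounding
        out = out[tuple(slice(0, t) for t in target_shape)]
    return out


def grad_cam(model: Backbone, image: np.ndarray, target_class: int,
             brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Raw Grad-CAM map for one input volume on the input grid."""
    n_classes = len(model.spec["classes"])
    if not 0 <= target_class < n_classes:
        raise IndexError(f"class index {target_class} out of range 0..{n_classes - 1}")
    model.set_training(False)
    x = np.asarray(image, dtype=np.float32)[None, None]
    logits = model(x)
    one_hot = np.zeros_like(logits)
    one_hot[0, target_class] = 1.0
    dfeat = model.backward_to_features(one_hot)     # (1, C, d, h, w)
    feat = model._features
    weights = dfeat.mean(axis=(2, 3, 4), keepdims=True)
    cam = np.maximum((weights * feat).sum(axis=1)[0], 0.0)
    cam = _upsample(cam, x.shape[2:])
    if brain_mask is not None:
        cam = np.where(brain_mask, cam, 0.0)
    return cam.astype(np.float32)


def minmax_normalize(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        logger.warning("constant saliency map; returning all zeros")
        return np.zeros_like(data, dtype=np.float32)
    return ((data - lo) / (hi - lo)).astype(np.float32)


def class_mean_saliency(model: Backbone, images: dict, true_labels: dict,
                        predicted_labels: dict, class_label: str,
                        brain_mask: np.ndarray | None = None) -> SaliencyMap | None:
    """Average Grad-CAM maps over correctly classified subjects of one
    class, then min-max normalize; None when no subject qualifies."""
    classes = model.spec["classes"]
    if class_label not in classes:
        raise ValueError(f"{class_label!r} not among model classes {classes}")
    target = classes.index(class_label)
    correct = [sid for sid, lab in true_labels.items()
               if lab == class_label and predicted_labels.get(sid) == class_label]
    if not correct:
        return None
    acc = None
    for sid in correct:
        cam = grad_cam(model, images[sid], target, brain_mask=brain_mask)
        acc = cam if acc is None else acc + cam
    mean_map = acc / len(correct)
    return SaliencyMap(data=minmax_normalize(mean_map),
                       model_name=model.spec["name"], class_label=class_label,
                       n_subjects=len(correct))


def model_level_saliency(model: Backbone, images: dict, true_labels: dict,
                         predicted_labels: dict,
                         brain_mask: np.ndarray | None = None) -> SaliencyMap | None:
    """Model-level map: class-mean maps of every class, averaged with
    weights proportional to the number of correctly classified subjects,
    then min-max normalized.  Summarizes where the model as a whole
    attends, independent of which class the evidence argues for."""
    acc, total = None, 0
    for cls in model.spec["classes"]:
        smap = class_mean_saliency(model, images, true_labels,
                                   predicted_labels, cls, brain_mask=brain_mask)
        if smap is None:
            continue
        weighted = smap.data * smap.n_subjects
        acc = weighted if acc is None else acc + weighted
        total += smap.n_subjects
    if acc is None:
        return None
    return SaliencyMap(data=minmax_normalize(acc / total),
                       model_name=model.spec["name"], class_label="all",
                       n_subjects=total)


def extract_rois(saliency: SaliencyMap | np.ndarray, atlas: PhantomAtlas,
                 threshold: float = DEFAULT_ROI_THRESHOLD) -> list[ROIRow]:
    """Regions with any voxel above threshold, sorted by peak descending.

    Laterality uses the midline of the declared left-right axis; a region
    exceeding the threshold on both sides is "bilateral", and the voxel
    fraction is computed over the qualifying side(s) only.
    """
    data = saliency.data if isinstance(saliency, SaliencyMap) else saliency
    if data.shape != atlas.shape:
        raise ValueError(f"grid mismatch: saliency {data.shape} vs atlas {atlas.shape}")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    mid = data.shape[LR_AXIS] / 2.0
    coords = np.arange(data.shape[LR_AXIS])
    left_sel = coords < mid
    shape_sel = [None] * 3
    shape_sel[LR_AXIS] = slice(None)
    left_side = np.zeros(data.shape, dtype=bool)
    left_side[left_sel, :, :] = True  # LR_AXIS == 0

    rows = []
    for name in sorted(atlas.names()):
        region = atlas.mask_for(name)
        hot = region & (data > threshold)
        if not hot.any():
            continue
        sides = []
        if (hot & left_side).any():
            sides.append("left")
        if (hot & ~left_side).any():
            sides.append("right")
        laterality = "bilateral" if len(sides) == 2 else sides[0]
        qualifying = np.zeros(data.shape, dtype=bool)
        if "left" in sides:
            qualifying |= region & left_side
        if "right" in sides:
            qualifying |= region & ~left_side
        rows.append(ROIRow(region=name, laterality=laterality,
                           peak=float(data[region].max()),
                           voxel_fraction=float(hot.sum() / qualifying.sum())))
    rows.sort(key=lambda r: -r.peak)
    return rows


def roi_report_table(rows: list[ROIRow]):
    import pandas as pd
    return pd.DataFrame([{"region": r.region, "laterality": r.laterality,
                          "peak": r.peak, "voxel_fraction": r.voxel_fraction}
                         for r in rows])
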