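"""Training-time augmentation: same-class mix-up, horizontal flip, rotation.

Each technique fires independently with probability ``apply_prob``
(default 10%) per sample per epoch, in the fixed order
mix-up -> flip -> rotation.  Mix-up blends two same-class images with a
weight drawn uniformly from (0, 1), so class labels stay hard; the flip
mirrors the declared left-right axis; rotations are drawn uniformly in
[-max_rotation_deg, +max_rotation_deg] about one uniformly chosen grid
axis, with trilinear interpolation and zero fill.

Augmentation is used on the training split only — validation and test
loaders never call into this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import rotate as nd_rotate

from .io import LR_AXIS

_ROTATION_PLANES = ((1, 2), (0, 2), (0, 1))  # plane of rotation about axis 0/1/2


@dataclass
class AugmentConfig:
    apply_prob: float = 0.10
    max_rotation_deg: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must be in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")


def mixup(x1: np.ndarray, x2: np.ndarray, alpha: float) -> np.ndarray:
    """Voxelwise convex combination alpha*x1 + (1-alpha)*x2."""
    x1 = np.asarray(x1, dtype=np.float32)
    x2 = np.asarray(x2, dtype=np.float32)
    if x1.shape != x2.shape:
        raise ValueError(f"grid mismatch: {x1.shape} vs {x2.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return (alpha * x1 + (1.0 - alpha) * x2).astype(np.float32)


def horizontal_flip(x: np.ndarray) -> np.ndarray:
    """Mirror along the declared left-right axis."""
    return np.flip(np.asarray(x), axis=LR_AXIS).copy()


def random_rotation(x: np.ndarray, max_deg: float, rng) -> np.ndarray:
    """Rotate by a uniform angle in [-max_deg, +max_deg] about a uniformly
    chosen grid axis; trilinear interpolation, zero fill; 0 degrees is the
    identity."""
    if max_deg < 0:
        raise ValueError("max_deg must be >= 0")
    axis = int(rng.integers(0, 3))
    angle = float(rng.uniform(-max_deg, max_deg))
    if angle == 0.0 or max_deg == 0.0:
        return np.asarray(x, dtype=np.float32).copy()
    out = nd_rotate(np.asarray(x, dtype=np.float32), angle,
                    axes=_ROTATION_PLANES[axis], reshape=False, order=1,
                    mode="constant", cval=0.0)
    return out.astype(np.float32)


def augment_volumes(volumes: list[np.ndarray], pools: list[list[np.ndarray]],
                    cfg: AugmentConfig, rng, return_applied: bool = False):
    """Jointly augment aligned image channels of one subject.

    ``volumes`` are the image(s) the model consumes (e.g. SUVR alone, or
    SUVR and SRP for the multiclass model); ``pools`` gives, per channel,
    the same-class candidates for mix-up, indexed consistently so one
    partner draw blends every channel of the same partner subject.  All
    stochastic decisions (fire/not, partner, alpha, flip, angle) are drawn
    once and shared across channels, keeping the channels aligned.
    """
    vols = [np.asarray(v, dtype=np.float32) for v in volumes]
    applied = {"mixup": False, "flip": False, "rotation": False}

    if rng.random() < cfg.apply_prob:
        pool_size = len(pools[0]) if pools else 0
        if pool_size == 0:
            import logging
            logging.getLogger(__name__).warning(
                "mix-up fired but the same-class pool is empty; skipping")
        else:
            partner = int(rng.integers(0, pool_size))
            alpha = float(rng.uniform(0.0, 1.0))
            vols = [mixup(v, pool[partner], alpha)
                    for v, pool in zip(vols, pools)]
            applied["mixup"] = True

    if rng.random() < cfg.apply_prob:
        vols = [horizontal_flip(v) for v in vols]
        applied["flip"] = True

    if rng.random() < cfg.apply_prob:
        axis = int(rng.integers(0, 3))
        angle = float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
        if angle != 0.0:
            vols = [nd_rotate(v, angle, axes=_ROTATION_PLANES[axis],
                              reshape=False, order=1, mode="constant",
                              cval=0.0).astype(np.float32) for v in vols]
        applied["rotation"] = True

    if return_applied:
        return vols, applied
    return vols


def augment_sample(x: np.ndarray, same_class_pool: list[np.ndarray],
                   cfg: AugmentConfig, rng, return_applied: bool = False):
    """Single-image convenience wrapper around :func:`augment_volumes`."""
    result = augment_volumes([x], [same_class_pool], cfg, rng,
                             return_applied=return_applied)
    if return_applied:
        vols, applied = result
        return vols[0], applied
    return result[0]
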