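"""Cohort splitting and model training.

Splits are per-class 70/10/20 train/val/test with largest-remainder
rounding.  All models train with cross-entropy under Adam; augmentation
(mix-up, flip, rotation) applies to training samples only.  Each binary
model sees only the two classes of its task; the multiclass model trains
its head (and, unless unfrozen, nothing else beyond the added
convolutions) on the AD/DLB/Mixed training subjects.  Checkpoint
selection is by best validation loss with early stopping.

Rows flagged ``train_only`` in the manifest (appended external cohorts)
are forced into the training split and never reach validation or test.
"""

from __future__ import annotations

import copy
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, augment_volumes
from .io import CLASSES, CohortManifest, ModelBundle, read_volume, save_bundle
from .nets import (BINARY_MODEL_NAMES, EXTRACTOR_ORDER, MULTICLASS_MODEL_NAME,
                   Backbone, FeatureExtractor, MulticlassModel,
                   build_multiclass_model, bundle_from_model, make_model_spec,
                   model_from_bundle)

logger = logging.getLogger(__name__)

SPLIT_FRACTIONS = {"train": 0.70, "val": 0.10, "test": 0.20}


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 8
    optimizer: str = "adam"
    lr: float = 1e-4
    seed: int = 0
    freeze_extractors: bool = True
    patience: int = 10
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    remainder = n - sum(base)
    # ties go to the smaller fraction so no split starves at small n
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - base[i]), fractions[i]))
    for i in range(remainder):
        base[order[i]] += 1
    return base


def assign_splits(labels, seed: int, fractions=None) -> list[str]:
    """Per-class largest-remainder train/val/test assignment."""
    fractions = fractions or SPLIT_FRACTIONS
    names = list(fractions)
    fracs = [fractions[k] for k in names]
    labels = list(labels)
    rng = np.random.default_rng([int(seed), 0x5917])
    out = [""] * len(labels)
    for cls in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == cls]
        rng.shuffle(idx)
        counts = _largest_remainder_counts(len(idx), fracs)
        pos = 0
        for name, count in zip(names, counts):
            for i in idx[pos:pos + count]:
                out[i] = name
            pos += count
    return out


def split_cohort(manifest: CohortManifest, seed: int) -> CohortManifest:
    """Assign 70/10/20 splits per class; ``train_only`` rows go to train."""
    df = manifest.table
    train_only = df.get("train_only")
    locked = (train_only.astype(str).str.lower().isin(("true", "1", "yes"))
              if train_only is not None else np.zeros(len(df), dtype=bool))
    pool = df[~locked]
    counts = pool["label"].value_counts()
    thin = [c for c in counts.index if counts[c] < 3]
    if thin:
        raise ValueError(f"class(es) with fewer than 3 subjects: {thin}")
    splits = assign_splits(pool["label"].tolist(), seed)
    out = df.copy()
    out.loc[~locked, "split"] = splits
    out.loc[locked, "split"] = "train"
    return CohortManifest(out)


# ---------------------------------------------------------------------------
# Image loading
# ---------------------------------------------------------------------------

_PATH_COLUMN = {"suvr": "suvr_path", "srp": "srp_path"}


def load_images(manifest: CohortManifest, image_types) -> dict:
    """Read the preprocessed image(s) of every subject into memory.

    Returns subject_id -> {image_type: float32 array}.
    """
    for t in image_types:
        if _PATH_COLUMN[t] not in manifest.table.columns:
            raise ValueError(
                f"manifest has no {_PATH_COLUMN[t]!r} column; run preprocess_cohort first")
    images = {}
    for row in manifest.rows():
        images[row.subject_id] = {
            t: read_volume(getattr(row, _PATH_COLUMN[t])).data
            for t in image_types
        }
    return images


# ---------------------------------------------------------------------------
# Core training loop
# ---------------------------------------------------------------------------

def _forward(model, batch):
    if isinstance(model, MulticlassModel):
        return model(batch["suvr"], batch["srp"])
    (only,) = batch.values()
    return model(only)


def _stack(images, ids, image_types):
    return {t: np.stack([images[i][t] for i in ids])[:, None].astype(np.float32)
            for t in image_types}


def _evaluate_loss(model, images, rows, image_types, class_index,
                   batch_size) -> tuple[float, float]:
    model.set_training(False)
    ids = [r.subject_id for r in rows]
    labels = np.array([class_index[r.label] for r in rows])
    losses, correct = [], 0
    for start in range(0, len(ids), batch_size):
        chunk = ids[start:start + batch_size]
        batch = _stack(images, chunk, image_types)
        logits = _forward(model, batch)
        loss, _ = nn.softmax_cross_entropy(logits, labels[start:start + len(chunk)])
        losses.append(loss * len(chunk))
        correct += int((logits.argmax(axis=1) ==
                        labels[start:start + len(chunk)]).sum())
    return float(np.sum(losses) / len(ids)), correct / len(ids)


def _fit(model, manifest, cfg: TrainConfig, classes, image_types,
         trainable_params=None, rng_tag: int = 0):
    """Shared Adam training loop with augmentation and early stopping."""
    class_index = {c: i for i, c in enumerate(classes)}
    train_rows = list(manifest.subset(split="train", labels=classes).rows())
    val_rows = list(manifest.subset(split="val", labels=classes).rows())
    present = {r.label for r in train_rows}
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"training split has no subjects for class(es): {missing}")
    if not val_rows:
        raise ValueError("validation split is empty")

    images = load_images(manifest, image_types)
    rng = np.random.default_rng([cfg.seed, rng_tag, 0x7A17])

    # same-class mix-up pools over the *training* subjects, per image type
    pool_ids = {c: [r.subject_id for r in train_rows if r.label == c]
                for c in classes}
    pools = {c: {t: [images[i][t] for i in pool_ids[c]] for t in image_types}
             for c in classes}

    params = trainable_params if trainable_params is not None else model.params()
    opt = nn.Adam(params, lr=cfg.lr)

    best_loss, best_state, best_epoch, since_best = np.inf, None, -1, 0
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    for epoch in range(cfg.epochs):
        model.set_training(True)
        order = rng.permutation(len(train_rows))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            rows = [train_rows[i] for i in order[start:start + cfg.batch_size]]
            arrays = {t: [] for t in image_types}
            labels = []
            for r in rows:
                vols = [images[r.subject_id][t] for t in image_types]
                vols = augment_volumes(
                    vols, [pools[r.label][t] for t in image_types],
                    cfg.augment, rng)
                for t, v in zip(image_types, vols):
                    arrays[t].append(v)
                labels.append(class_index[r.label])
            batch = {t: np.stack(arrays[t])[:, None].astype(np.float32)
                     for t in image_types}
            labels = np.array(labels)
            logits = _forward(model, batch)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels)
            opt.zero_grad()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}")
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(rows)
        history["train_loss"].append(epoch_loss / len(train_rows))

        val_loss, val_acc = _evaluate_loss(model, images, val_rows, image_types,
                                           class_index, cfg.batch_size)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss - 1e-9:
            best_loss, best_epoch, since_best = val_loss, epoch, 0
            best_state = [p.data.copy() for p in model.params()]
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_loss)
    return history


def train_binary(spec: dict, manifest: CohortManifest, cfg: TrainConfig,
                 init: str = "he_random",
                 pretrained_bundle: ModelBundle | None = None,
                 preprocessing_stats: dict | None = None) -> ModelBundle:
    """Train one binary classifier on the two classes of its spec."""
    from .nets import build_backbone

    if spec["kind"] != "binary":
        raise ValueError("train_binary requires a binary model spec")
    seed_tag = zlib.crc32(spec["name"].encode())
    model = build_backbone(spec, init=init, seed=cfg.seed + seed_tag % 1000,
                           pretrained_bundle=pretrained_bundle)
    history = _fit(model, manifest, cfg, tuple(spec["classes"]),
                   tuple(spec["image_types"]), rng_tag=seed_tag)
    return bundle_from_model(model, preprocessing_stats=preprocessing_stats,
                             history=history)


def train_multiclass(extractor_bundles: list[ModelBundle],
                     manifest: CohortManifest, cfg: TrainConfig,
                     preprocessing_stats: dict | None = None) -> ModelBundle:
    """Train the AD/DLB/Mixed head over six binary-model feature extractors.

    ``extractor_bundles`` must be the six trained binary bundles in the
    fixed order (AD-HC_suvr, DLB-HC_suvr, Mixed-HC_suvr, AD-HC_srp,
    DLB-HC_srp, Mixed-HC_srp).
    """
    names = [b.spec["name"] for b in extractor_bundles]
    if tuple(names) != EXTRACTOR_ORDER:
        raise ValueError(
            f"extractor bundles must be ordered {EXTRACTOR_ORDER}, got {tuple(names)}")
    extractors = []
    for i, b in enumerate(extractor_bundles):
        backbone = model_from_bundle(b, seed=cfg.seed)
        extractors.append(FeatureExtractor(backbone, seed=cfg.seed + i))
    model = build_multiclass_model(extractors, seed=cfg.seed,
                                   freeze_extractors=cfg.freeze_extractors)
    history = _fit(model, manifest, cfg, ("AD", "DLB", "Mixed"),
                   ("suvr", "srp"), trainable_params=model.trainable_params(),
                   rng_tag=zlib.crc32(b"multiclass"))
    return bundle_from_model(model, preprocessing_stats=preprocessing_stats,
                             history=history)


def train_ensemble(manifest: CohortManifest, cfg: TrainConfig,
                   grid=None, channels=None,
                   preprocessing_stats: dict | None = None,
                   out_dir=None) -> dict[str, ModelBundle]:
    """Train all seven binary models plus the multiclass model.

    Returns name -> bundle; optionally persists each bundle under
    ``out_dir/<name>``.
    """
    from .nets import DEFAULT_CHANNELS

    if grid is None:
        first = next(iter(manifest.rows()))
        grid = read_volume(first.suvr_path).shape
    channels = channels or DEFAULT_CHANNELS

    bundles: dict[str, ModelBundle] = {}
    for name in BINARY_MODEL_NAMES:
        spec = make_model_spec(name, grid=grid, channels=channels)
        logger.info("training %s", name)
        bundles[name] = train_binary(spec, manifest, cfg,
                                     preprocessing_stats=preprocessing_stats)
    extractor_bundles = [bundles[n] for n in EXTRACTOR_ORDER]
    logger.info("training %s", MULTICLASS_MODEL_NAME)
    bundles[MULTICLASS_MODEL_NAME] = train_multiclass(
        extractor_bundles, manifest, cfg,
        preprocessing_stats=preprocessing_stats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for name, b in bundles.items():
            save_bundle(b, out_dir / name)
    return bundles


# ---------------------------------------------------------------------------
# 5-fold cross-validation
# ---------------------------------------------------------------------------

def make_fold_assignment(manifest: CohortManifest, n_folds: int = 5,
                         seed: int = 0) -> dict[str, int]:
    """Stratified fold indices over the non-test pool (test is excluded)."""
    pool = manifest.table[manifest.table["split"] != "test"]
    rng = np.random.default_rng([int(seed), 0xF01D])
    folds: dict[str, int] = {}
    for cls in sorted(pool["label"].unique()):
        ids = pool[pool["label"] == cls]["subject_id"].tolist()
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            folds[sid] = i % n_folds
    return folds


def cross_validate(manifest: CohortManifest, cfg: TrainConfig,
                   preprocess_config=None, n_folds: int = 5,
                   grid=None, channels=None, out_root=None):
    """Train the full ensemble once per fold and evaluate each on the
    fixed held-out test set.

    For each fold, the fold's subjects form the validation split and the
    remaining non-test subjects the training split; preprocessing
    statistics are re-fit on each fold's training portion when a
    ``preprocess_config`` is given (leak-free), otherwise the manifest's
    existing SUVR/SRP volumes are reused.  Returns
    ``(fold_results, aggregate)`` where each fold result carries the
    trained bundles and the test-set metrics.
    """
    from .ensemble import aggregate_fold_metrics, evaluate
    from .preprocess import preprocess_cohort

    folds = make_fold_assignment(manifest, n_folds=n_folds, seed=cfg.seed)
    fold_results = []
    for k in range(n_folds):
        df = manifest.table.copy()
        non_test = df["split"] != "test"
        fold_of = df["subject_id"].map(folds)
        df.loc[non_test, "split"] = np.where(fold_of[non_test] == k, "val", "train")
        fold_manifest = CohortManifest(df)
        if preprocess_config is not None:
            pc = copy.copy(preprocess_config)
            pc.out_dir = str(Path(preprocess_config.out_dir) / f"fold{k}")
            fold_manifest = preprocess_cohort(fold_manifest, pc)
        out_dir = None if out_root is None else Path(out_root) / f"fold{k}"
        bundles = train_ensemble(fold_manifest, cfg, grid=grid,
                                 channels=channels, out_dir=out_dir)
        metrics = evaluate(fold_manifest.subset(split="test"), bundles)
        fold_results.append({"fold": k, "manifest": fold_manifest,
                             "bundles": bundles, "metrics": metrics})
    aggregate = aggregate_fold_metrics([r["metrics"] for r in fold_results])
    return fold_results, aggregate
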