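"""Shared fixtures: phantom cohorts and a trained ensemble.

The heavyweight fixtures are session-scoped so that the recovery-style
tests (ensemble metrics, saliency localization, training properties)
share one simulation + training run each.
"""

from pathlib import Path

import numpy as np
import pytest

from fdgpet import phantom, preprocess, train
from fdgpet.augment import AugmentConfig

STUDY_GRID = (32, 32, 32)
# training configuration for desk-scale recovery runs
RECOVERY_CFG = dict(epochs=60, lr=1e-3, batch_size=8, seed=1, patience=20)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """10 subjects/class at the study conditions; preprocessed."""
    root = tmp_path_factory.mktemp("small_cohort")
    params = phantom.PhantomParams(seed=7)
    manifest, atlas = phantom.simulate_cohort(
        {"AD": 10, "DLB": 10, "Mixed": 10, "HC": 10}, params, root / "cohort")
    cfg = preprocess.PreprocessConfig(out_dir=str(root / "prep"),
                                      atlas_dir=str(root / "cohort"))
    manifest = preprocess.preprocess_cohort(manifest, cfg)
    return {"manifest": manifest, "atlas": atlas, "root": root,
            "params": params}


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """The full study-condition cohort: 40/40/40/20 subjects, effect 0.7,
    noise sd 5, 32^3 grid; preprocessed with train-only statistics."""
    root = tmp_path_factory.mktemp("study_cohort")
    params = phantom.PhantomParams(seed=11)
    manifest, atlas = phantom.simulate_cohort(
        {"AD": 40, "DLB": 40, "Mixed": 40, "HC": 20}, params, root / "cohort")
    cfg = preprocess.PreprocessConfig(out_dir=str(root / "prep"),
                                      atlas_dir=str(root / "cohort"))
    manifest = preprocess.preprocess_cohort(manifest, cfg)
    return {"manifest": manifest, "atlas": atlas, "root": root,
            "params": params}


@pytest.fixture(scope="session")
def trained_ensemble(study_cohort):
    """All seven binary models + the multiclass model trained on the
    study cohort (the expensive session fixture)."""
    cfg = train.TrainConfig(augment=AugmentConfig(rng_seed=1), **RECOVERY_CFG)
    bundles = train.train_ensemble(study_cohort["manifest"], cfg)
    return {"bundles": bundles, "cfg": cfg, **study_cohort}
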