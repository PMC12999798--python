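"""Three-step hierarchical ensemble inference and class-wise evaluation.

Decision rule per subject:

1. The SUVR image goes to the AD-HC and Mixed-HC SUVR models, the SRP
   image to the DLB-HC SRP model.  If all three vote HC, the subject is
   HC and inference stops.
2. Otherwise the multiclass AD/DLB/Mixed model runs; if its argmax is
   DLB, the subject is DLB and inference stops.
3. Otherwise the dedicated AD-Mixed SUVR model decides AD versus Mixed,
   regardless of the multiclass AD/Mixed preference.

For ROC analysis the hard-gated rule needs a continuous per-class score;
the composed chain product used here is a documented construction of this
package (the gating itself defines no score): HC = product of the three
step-1 HC probabilities, DLB = (1 - HC) * P_mc(DLB), AD/Mixed =
(1 - HC) * (1 - P_mc(DLB)) * P_am(AD or Mixed).  The four scores sum to 1
whenever each model's probabilities do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .io import CLASSES, CohortManifest, read_volume
from .nets import MulticlassModel, model_from_bundle

STEP1_MODELS = ("AD-HC_suvr", "Mixed-HC_suvr", "DLB-HC_srp")
EVAL_MODELS = STEP1_MODELS + ("AD-DLB-Mixed_suvr_srp", "AD-Mixed_suvr")

SCORE_ORDER = ("HC", "AD", "DLB", "Mixed")


@dataclass
class EnsemblePrediction:
    subject_id: str
    step1_votes: dict          # model name -> "HC" or the dementia class
    step2_label: str | None    # multiclass argmax, or None if gated out
    step3_label: str | None    # AD-Mixed decision, or None
    final_label: str
    scores: dict               # class -> composed score


def decide_label(step1_hc_votes, multiclass_argmax: str,
                 admixed_argmax: str):
    """Pure decision table; returns (final, step2_label, step3_label).

    ``step1_hc_votes`` are the three booleans "model voted HC";
    ``multiclass_argmax`` is in {AD, DLB, Mixed}; ``admixed_argmax`` in
    {AD, Mixed}.  Steps 2/3 are None when gating stops earlier.
    """
    if all(step1_hc_votes):
        return "HC", None, None
    if multiclass_argmax == "DLB":
        return "DLB", multiclass_argmax, None
    return admixed_argmax, multiclass_argmax, admixed_argmax


def class_scores(step1_hc_probs, multiclass_probs, admixed_probs) -> dict:
    """Composed 4-class score vector from per-model probabilities.

    ``step1_hc_probs``: HC probabilities of the three step-1 models;
    ``multiclass_probs``: (AD, DLB, Mixed); ``admixed_probs``: (AD, Mixed).
    """
    for p in (*step1_hc_probs, *multiclass_probs, *admixed_probs):
        if not 0.0 <= p <= 1.0 + 1e-9:
            raise ValueError(f"probability outside [0, 1]: {p}")
    hc = float(np.prod(step1_hc_probs))
    p_dlb = float(multiclass_probs[1])
    rest = (1.0 - hc)
    return {
        "HC": hc,
        "DLB": rest * p_dlb,
        "AD": rest * (1.0 - p_dlb) * float(admixed_probs[0]),
        "Mixed": rest * (1.0 - p_dlb) * float(admixed_probs[1]),
    }


def _model_probs(model, suvr, srp) -> np.ndarray:
    if model.spec.get("kind") == "multiclass":
        logits = model(suvr[None, None], srp[None, None])
    else:
        image = suvr if model.spec["image_types"] == ["suvr"] else srp
        logits = model(image[None, None])
    return nn.softmax(np.asarray(logits, dtype=np.float64))[0]


def _as_models(bundles: dict) -> dict:
    missing = [n for n in EVAL_MODELS if n not in bundles]
    if missing:
        raise ValueError(f"missing evaluation model(s): {missing}")
    out = {}
    for name in EVAL_MODELS:
        entry = bundles[name]
        out[name] = (entry if hasattr(entry, "forward")
                     else model_from_bundle(entry))
        out[name].set_training(False)
    return out


def predict_subject(suvr: np.ndarray, srp: np.ndarray, bundles: dict,
                    subject_id: str = "") -> EnsemblePrediction:
    """Run the three-step ensemble for one subject.

    ``bundles`` maps the five evaluation model names to either
    :class:`~fdgpet.io.ModelBundle` objects or already-built models.
    """
    models = _as_models(bundles)
    suvr = np.asarray(suvr, dtype=np.float32)
    srp = np.asarray(srp, dtype=np.float32)
    if suvr.shape != srp.shape:
        raise ValueError(f"grid mismatch: {suvr.shape} vs {srp.shape}")

    votes, hc_probs = {}, []
    for name in STEP1_MODELS:
        model = models[name]
        probs = _model_probs(model, suvr, srp)
        classes = model.spec["classes"]
        hc_idx = classes.index("HC")
        votes[name] = classes[int(np.argmax(probs))]
        hc_probs.append(float(probs[hc_idx]))

    mc_probs = _model_probs(models["AD-DLB-Mixed_suvr_srp"], suvr, srp)
    mc_classes = models["AD-DLB-Mixed_suvr_srp"].spec["classes"]
    mc_argmax = mc_classes[int(np.argmax(mc_probs))]

    am_probs = _model_probs(models["AD-Mixed_suvr"], suvr, srp)
    am_classes = models["AD-Mixed_suvr"].spec["classes"]
    am_argmax = am_classes[int(np.argmax(am_probs))]

    final, step2, step3 = decide_label(
        [votes[n] == "HC" for n in STEP1_MODELS], mc_argmax, am_argmax)
    ordered_mc = [mc_probs[mc_classes.index(c)] for c in ("AD", "DLB", "Mixed")]
    ordered_am = [am_probs[am_classes.index(c)] for c in ("AD", "Mixed")]
    scores = class_scores(hc_probs, ordered_mc, ordered_am)
    return EnsemblePrediction(subject_id=subject_id, step1_votes=votes,
                              step2_label=step2, step3_label=step3,
                              final_label=final, scores=scores)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    def ratio(a, b):
        return a / b if b else float("nan")
    return {"sensitivity": ratio(tp, tp + fn), "specificity": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp), "npv": ratio(tn, tn + fn)}


def evaluate(test_manifest: CohortManifest, bundles: dict) -> dict:
    """Ensemble predictions + one-vs-rest metrics on a test split.

    Returns a dict with the per-subject prediction table, the 4x4
    confusion matrix (rows = true class, columns = predicted), and per
    class sensitivity/specificity/PPV/NPV from final labels plus AUROC
    from the composed scores.  Metrics for a class absent from the test
    set are NaN, not zero.
    """
    if len(test_manifest) == 0:
        raise ValueError("test manifest is empty")
    models = _as_models(bundles)
    records = []
    for row in test_manifest.rows():
        suvr = read_volume(row.suvr_path).data
        srp = read_volume(row.srp_path).data
        pred = predict_subject(suvr, srp, models, subject_id=row.subject_id)
        rec = {"subject_id": row.subject_id, "true": row.label,
               "pred": pred.final_label,
               "step2": pred.step2_label, "step3": pred.step3_label}
        for name in STEP1_MODELS:
            rec[f"vote_{name}"] = pred.step1_votes[name]
        for c in SCORE_ORDER:
            rec[f"score_{c}"] = pred.scores[c]
        records.append(rec)
    table = pd.DataFrame(records)

    confusion = np.zeros((4, 4), dtype=int)
    cls_idx = {c: i for i, c in enumerate(CLASSES)}
    for _, r in table.iterrows():
        confusion[cls_idx[r["true"]], cls_idx[r["pred"]]] += 1

    per_class = {}
    for c in CLASSES:
        pos = table["true"] == c
        hit = table["pred"] == c
        m = binary_metrics(tp=int((pos & hit).sum()), fn=int((pos & ~hit).sum()),
                           fp=int((~pos & hit).sum()), tn=int((~pos & ~hit).sum()))
        if pos.any() and (~pos).any():
            m["auroc"] = float(roc_auc_score(pos.astype(int),
                                             table[f"score_{c}"]))
        else:
            m["auroc"] = float("nan")
        if not pos.any():
            m = {k: float("nan") for k in m}
        per_class[c] = m

    return {"predictions": table, "confusion": confusion, "per_class": per_class}


def aggregate_fold_metrics(fold_metrics: list[dict]) -> dict:
    """Across-fold mean and normal-approximation 95% CI per class/metric."""
    out = {}
    n = len(fold_metrics)
    for c in CLASSES:
        out[c] = {}
        keys = fold_metrics[0]["per_class"][c].keys()
        for k in keys:
            vals = np.array([m["per_class"][c][k] for m in fold_metrics],
                            dtype=float)
            mean = float(np.nanmean(vals))
            sd = float(np.nanstd(vals, ddof=1)) if n > 1 else float("nan")
            half = 1.96 * sd / np.sqrt(n) if n > 1 else float("nan")
            out[c][k] = {"mean": mean, "ci95": (mean - half, mean + half)}
    return out
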