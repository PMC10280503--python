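"""End-to-end evaluation of a trained pipeline on a labelled dataset."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics
from .classification import classify_features
from .features import abcd_features
from .segmentation import SegmenterModel, segment_image
from .synthetic import SyntheticSample


def evaluate_split(
    segmenter: SegmenterModel,
    classifier,
    samples: Sequence[SyntheticSample],
) -> Tuple[pd.DataFrame, dict]:
    """Segment and classify every sample; return per-image rows + aggregates.

    Per-image rows carry Dice/IoU against the true mask and the predicted
    and true labels (classification uses the predicted mask's ABCD
    features; an empty predicted mask falls back to the full frame).
    Aggregates pool the label confusion counts and report both metric
    modes, plus mean Dice/IoU and balanced accuracy.
    """
    rows = []
    for i, sample in enumerate(samples):
        pred_mask, _ = segment_image(segmenter, sample.image)
        d = metrics.dice(pred_mask, sample.mask)
        j = metrics.iou(pred_mask, sample.mask)
        cls_mask = pred_mask if pred_mask.any() else np.ones_like(
            sample.mask, dtype=bool)
        pred = classify_features(classifier, abcd_features(sample.image, cls_mask))
        rows.append({
            "image_id": f"sample_{i:05d}",
            "dice": d,
            "iou": j,
            "predicted_label": pred.label,
            "malignant_posterior": pred.malignant_posterior,
            "true_label": sample.label,
        })
    per_image = pd.DataFrame(rows)

    counts = metrics.confusion_from_labels(
        per_image["predicted_label"], per_image["true_label"])

    def _safe_report(mode: str) -> dict:
        # a degenerate confusion matrix (e.g. no positive predictions)
        # yields NaN for the undefined entries instead of failing the run
        try:
            return metrics.report(counts, mode).as_dict()
        except ValueError:
            out = {"mode": mode}
            for name, fn in (
                ("accuracy", lambda: metrics.accuracy(counts)),
                ("sensitivity", lambda: metrics.sensitivity(counts, mode)),
                ("specificity", lambda: metrics.specificity(counts, mode)),
                ("precision", lambda: metrics.precision(counts)),
            ):
                try:
                    out[name] = fn()
                except ValueError:
                    out[name] = float("nan")
            try:
                out["f1"] = metrics.f1_score(out["precision"], out["sensitivity"])
            except ValueError:
                out["f1"] = float("nan")
            return out

    aggregate = {
        "mean_dice": float(per_image["dice"].mean()),
        "mean_iou": float(per_image["iou"].mean()),
        "balanced_accuracy": metrics.balanced_accuracy(
            per_image["predicted_label"], per_image["true_label"]),
        "confusion": {"tp": counts.tp, "tn": counts.tn,
                      "fp": counts.fp, "fn": counts.fn},
        "standard": _safe_report("standard"),
        "paper_fidelity": _safe_report("paper_fidelity"),
    }
    return per_image, aggregate
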