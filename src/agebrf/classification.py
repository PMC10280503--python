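"""Lesion-level benign/malignant classification from ABCD features."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .features import LesionFeatureVector, LesionMask, abcd_features, validate_mask
from .forest import ForestHyperparams, ForestModel, predict_proba, train_forest

BENIGN, MALIGNANT = "benign", "malignant"
_LABEL_TO_INT = {BENIGN: 0, MALIGNANT: 1}


@dataclass(frozen=True)
class LesionPrediction:
    """Binary verdict; ties (posterior exactly 0.5) resolve to benign."""

    label: str
    malignant_posterior: float
    features: Optional[LesionFeatureVector] = None

    def __post_init__(self):
        if not (0.0 <= self.malignant_posterior <= 1.0):
            raise ValueError("posterior must be in [0, 1]")
        expected = MALIGNANT if self.malignant_posterior > 0.5 else BENIGN
        if self.label != expected:
            raise ValueError("label inconsistent with posterior and tie rule")


def prediction_from_posterior(
    posterior: float, features: Optional[LesionFeatureVector] = None
) -> LesionPrediction:
    label = MALIGNANT if posterior > 0.5 else BENIGN
    return LesionPrediction(label, float(posterior), features)


def feature_matrix(vectors: Sequence[LesionFeatureVector]) -> np.ndarray:
    return np.vstack([v.to_array() for v in vectors])


def train_classifier(
    feature_vectors: Sequence[LesionFeatureVector],
    labels: Sequence[str],
    hp: ForestHyperparams,
) -> ForestModel:
    """Forest on the flattened 10-column ABCD matrix."""
    if len(feature_vectors) != len(labels):
        raise ValueError("feature vectors and labels must be aligned")
    y = np.array([_LABEL_TO_INT[l] for l in labels], dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("both benign and malignant examples are required")
    return train_forest(feature_matrix(feature_vectors), y, hp)


def classify_features(model: ForestModel,
                      fv: LesionFeatureVector) -> LesionPrediction:
    proba = predict_proba(model, fv.to_array())
    malignant_col = model.classes.index(1)
    return prediction_from_posterior(float(proba[0, malignant_col]), fv)


def classify_lesion(model: ForestModel, image: np.ndarray,
                    mask: LesionMask) -> LesionPrediction:
    """ABCD features of the masked lesion -> forest posterior -> verdict."""
    mask = validate_mask(mask)
    if not mask.any():
        raise ValueError(
            "empty lesion mask: run segmentation first to obtain a lesion region"
        )
    return classify_features(model, abcd_features(image, mask))
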