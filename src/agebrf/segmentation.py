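"""Pixel-wise random-forest lesion segmentation.

A forest is trained on per-pixel feature vectors sampled from training
images (stratified half lesion / half background where available) and
applied to every pixel of a new image, giving a lesion-posterior map.  The
map is offset by the model's additive posterior bias, thresholded, cleaned
by morphological opening-then-closing with a disk, and optionally reduced
to its largest 8-connected component.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure, morphology

from ._rng import substream
from .features import LesionMask, validate_mask
from .forest import ForestHyperparams, ForestModel, predict_proba, train_forest
from .preprocessing import (
    PIXEL_FEATURE_NAMES,
    PixelFeatureStack,
    RGBImage,
    pixel_features,
    preprocess,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    threshold: float = 0.5        # posterior cut on the lesion class
    morph_radius: int = 2         # disk radius for opening then closing
    keep_largest: bool = True

    def __post_init__(self):
        if not (0.2 <= self.threshold <= 0.8):
            raise ValueError("threshold must be in [0.2, 0.8]")
        if not (0 <= self.morph_radius <= 5):
            raise ValueError("morph_radius must be in [0, 5]")


@dataclass
class SegmenterModel:
    forest: ForestModel
    params: SegmentationParams
    feature_names: List[str] = field(default_factory=lambda: list(PIXEL_FEATURE_NAMES))
    median_radius: int = 1

    def __post_init__(self):
        if self.forest.feature_count != len(self.feature_names):
            raise ValueError("forest feature count does not match feature names")

    def to_json(self) -> str:
        return json.dumps({
            "forest": json.loads(self.forest.to_json()),
            "params": {
                "threshold": self.params.threshold,
                "morph_radius": self.params.morph_radius,
                "keep_largest": self.params.keep_largest,
            },
            "feature_names": self.feature_names,
            "median_radius": self.median_radius,
        })

    @classmethod
    def from_json(cls, text: str) -> "SegmenterModel":
        d = json.loads(text)
        return cls(
            forest=ForestModel.from_json(json.dumps(d["forest"])),
            params=SegmentationParams(**d["params"]),
            feature_names=list(d["feature_names"]),
            median_radius=int(d["median_radius"]),
        )


def sample_pixels(mask: LesionMask, pixels_per_image: int,
                  rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified pixel sample: coords (n, 2) and 0/1 labels.

    Half the budget goes to lesion pixels and half to background where both
    are available; a class with fewer pixels than its share yields its
    whole population and the remainder goes to the other class.
    """
    mask = validate_mask(mask)
    lesion = np.argwhere(mask)
    background = np.argwhere(~mask)
    half = pixels_per_image // 2
    n_les = min(half, len(lesion))
    n_bg = min(pixels_per_image - n_les, len(background))
    if n_les == 0:
        logger.info("mask has no lesion pixels; contributing background only")
    parts, labels = [], []
    if n_les > 0:
        idx = rng.choice(len(lesion), size=n_les, replace=False)
        parts.append(lesion[idx])
        labels.append(np.ones(n_les, dtype=np.int64))
    if n_bg > 0:
        idx = rng.choice(len(background), size=n_bg, replace=False)
        parts.append(background[idx])
        labels.append(np.zeros(n_bg, dtype=np.int64))
    return np.concatenate(parts), np.concatenate(labels)


def _image_stack(image: RGBImage, median_radius: int) -> PixelFeatureStack:
    return pixel_features(preprocess(image, median_radius))


def train_segmenter(
    images: Sequence[RGBImage],
    masks: Sequence[LesionMask],
    hp: ForestHyperparams,
    params: SegmentationParams,
    pixels_per_image: int = 500,
    median_radius: int = 1,
    posterior_bias: float = 0.0,
    feature_stacks: Optional[Sequence[PixelFeatureStack]] = None,
) -> SegmenterModel:
    """Train a pixel forest from stratified samples of the training masks."""
    if len(images) != len(masks):
        raise ValueError("images and masks must be aligned")
    if pixels_per_image < 100:
        raise ValueError("pixels_per_image must be >= 100")
    X_parts, y_parts = [], []
    for i, (image, mask) in enumerate(zip(images, masks)):
        mask = validate_mask(mask)
        if mask.shape != image.shape[:2]:
            raise ValueError(f"image/mask shape mismatch at index {i}")
        stack = feature_stacks[i] if feature_stacks is not None else _image_stack(
            image, median_radius)
        coords, labels = sample_pixels(
            mask, pixels_per_image, substream(hp.seed, "sampling", i))
        X_parts.append(stack.planes[coords[:, 0], coords[:, 1], :])
        y_parts.append(labels)
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    forest = train_forest(X, y, hp)
    forest.posterior_bias = posterior_bias
    return SegmenterModel(forest=forest, params=params,
                          median_radius=median_radius)


def postprocess_posterior(posterior: np.ndarray,
                          params: SegmentationParams) -> LesionMask:
    """Threshold, open/close with a disk, optionally keep the largest blob.

    Components are 8-connected; among equal-sized largest components the one
    whose first pixel in row-major order (the lexicographically smallest
    pixel) comes first is kept.  The empty mask is a legal output.
    """
    binary = posterior > params.threshold
    if params.morph_radius > 0:
        selem = morphology.disk(params.morph_radius)
        binary = morphology.opening(binary, selem)
        binary = morphology.closing(binary, selem)
    if params.keep_largest and binary.any():
        labels = measure.label(binary, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        # labels are assigned in row-major scan order, so the smallest label
        # among ties is the component with the lexicographically first pixel
        binary = labels == int(np.argmax(sizes))
    return binary


def segment_image(
    model: SegmenterModel,
    image: RGBImage,
    feature_stack: Optional[PixelFeatureStack] = None,
) -> Tuple[LesionMask, np.ndarray]:
    """Segment one image; returns (binary mask, lesion posterior map)."""
    stack = feature_stack if feature_stack is not None else _image_stack(
        image, model.median_radius)
    H, W = stack.planes.shape[:2]
    proba = predict_proba(model.forest, stack.matrix)
    lesion_col = model.forest.classes.index(1)
    posterior = proba[:, lesion_col].reshape(H, W)
    posterior = np.clip(posterior + model.forest.posterior_bias, 0.0, 1.0)
    return postprocess_posterior(posterior, model.params), posterior
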