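"""GEO-tuned segmentation/classification pipeline.

The Golden Eagle Optimizer searches an 11-dimensional hyperparameter vector
— segmentation forest (trees, depth, feature fraction, leaf size),
segmentation post-processing (posterior threshold, morphology radius), the
additive posterior bias, and the classification forest (same four fields) —
against a validation fitness.  An eagle's fitness is the joint loss

    1 - (w_seg * mean Dice  +  w_cls * balanced accuracy)

where Dice is measured between predicted and true masks on the validation
images and balanced accuracy compares benign/malignant verdicts computed
from the *predicted* masks' ABCD features.  One eagle is always initialized
at the documented default hyperparameters, so elitist memory guarantees the
tuned loss is never worse than the default loss.  Pixel feature stacks and
training-mask ABCD features are computed once and shared across all fitness
evaluations; only forest training, prediction and post-processing depend on
the search position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._rng import child_seed
from .classification import classify_features, train_classifier
from .features import abcd_features
from .forest import ForestHyperparams
from .geo import GEOConfig, GEOResult, SearchSpace, run_geo
from .metrics import balanced_accuracy, dice
from .preprocessing import pixel_features, preprocess
from .segmentation import (
    SegmentationParams,
    SegmenterModel,
    postprocess_posterior,
    train_segmenter,
)
from .synthetic import SyntheticSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessWeights:
    w_seg: float = 0.5
    w_cls: float = 0.5

    def __post_init__(self):
        if self.w_seg < 0 or self.w_cls < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.w_seg + self.w_cls - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class PipelineHyperparams:
    seg_forest: ForestHyperparams
    seg_params: SegmentationParams
    posterior_bias: float
    cls_forest: ForestHyperparams


DEFAULT_HYPERPARAMS = PipelineHyperparams(
    seg_forest=ForestHyperparams(
        n_trees=30, max_depth=12, feature_fraction=0.5, min_samples_leaf=2),
    seg_params=SegmentationParams(threshold=0.5, morph_radius=2,
                                  keep_largest=True),
    posterior_bias=0.0,
    cls_forest=ForestHyperparams(
        n_trees=60, max_depth=8, feature_fraction=0.6, min_samples_leaf=1),
)

# (name, lower, upper, integer-valued) for each search coordinate
BOUNDS = [
    ("seg_n_trees", 10, 200, True),
    ("seg_max_depth", 2, 20, True),
    ("seg_feature_fraction", 0.1, 1.0, False),
    ("seg_min_samples_leaf", 1, 20, True),
    ("threshold", 0.2, 0.8, False),
    ("morph_radius", 0, 5, True),
    ("posterior_bias", -0.2, 0.2, False),
    ("cls_n_trees", 10, 200, True),
    ("cls_max_depth", 2, 20, True),
    ("cls_feature_fraction", 0.1, 1.0, False),
    ("cls_min_samples_leaf", 1, 20, True),
]


def pipeline_search_space() -> SearchSpace:
    return SearchSpace(
        lower=np.array([b[1] for b in BOUNDS], dtype=float),
        upper=np.array([b[2] for b in BOUNDS], dtype=float),
    )


def _coord(value: float, lo: float, hi: float, integer: bool) -> float:
    v = round(value) if integer else value
    return int(min(max(v, lo), hi)) if integer else float(min(max(v, lo), hi))


def decode_position(position: Sequence[float], seed: int = 0) -> PipelineHyperparams:
    """Deterministic decode: round integer coordinates, clip all to bounds."""
    p = np.asarray(position, dtype=float)
    if p.shape != (len(BOUNDS),):
        raise ValueError(f"position must have {len(BOUNDS)} coordinates")
    v = {name: _coord(p[i], lo, hi, integer)
         for i, (name, lo, hi, integer) in enumerate(BOUNDS)}
    return PipelineHyperparams(
        seg_forest=ForestHyperparams(
            n_trees=v["seg_n_trees"], max_depth=v["seg_max_depth"],
            feature_fraction=v["seg_feature_fraction"],
            min_samples_leaf=v["seg_min_samples_leaf"],
            seed=child_seed(seed, "forest", 0)),
        seg_params=SegmentationParams(
            threshold=v["threshold"], morph_radius=v["morph_radius"],
            keep_largest=True),
        posterior_bias=v["posterior_bias"],
        cls_forest=ForestHyperparams(
            n_trees=v["cls_n_trees"], max_depth=v["cls_max_depth"],
            feature_fraction=v["cls_feature_fraction"],
            min_samples_leaf=v["cls_min_samples_leaf"],
            seed=child_seed(seed, "forest", 1)),
    )


def encode_hyperparams(php: PipelineHyperparams) -> np.ndarray:
    return np.array([
        php.seg_forest.n_trees, php.seg_forest.max_depth,
        php.seg_forest.feature_fraction, php.seg_forest.min_samples_leaf,
        php.seg_params.threshold, php.seg_params.morph_radius,
        php.posterior_bias,
        php.cls_forest.n_trees, php.cls_forest.max_depth,
        php.cls_forest.feature_fraction, php.cls_forest.min_samples_leaf,
    ], dtype=float)


class _PipelineData:
    """Feature caches shared across fitness evaluations."""

    def __init__(self, train_split: Sequence[SyntheticSample],
                 val_split: Sequence[SyntheticSample], median_radius: int = 1):
        if not train_split or not val_split:
            raise ValueError("splits must be nonempty")
        for name, split in (("train", train_split), ("val", val_split)):
            if len({s.label for s in split}) < 2:
                raise ValueError(f"{name} split contains a single class")
        self.train = list(train_split)
        self.val = list(val_split)
        self.median_radius = median_radius
        self.train_stacks = [
            pixel_features(preprocess(s.image, median_radius)) for s in self.train
        ]
        self.val_stacks = [
            pixel_features(preprocess(s.image, median_radius)) for s in self.val
        ]
        self.train_abcd = [abcd_features(s.image, s.mask) for s in self.train]
        self.train_labels = [s.label for s in self.train]
        self.val_labels = [s.label for s in self.val]


def _evaluate_hyperparams(
    php: PipelineHyperparams, data: _PipelineData, weights: FitnessWeights,
    pixels_per_image: int,
) -> Tuple[float, float, float]:
    """(loss, mean dice, balanced accuracy) of one hyperparameter vector."""
    segmenter = train_segmenter(
        [s.image for s in data.train], [s.mask for s in data.train],
        php.seg_forest, php.seg_params,
        pixels_per_image=pixels_per_image,
        median_radius=data.median_radius,
        posterior_bias=php.posterior_bias,
        feature_stacks=data.train_stacks,
    )
    classifier = train_classifier(data.train_abcd, data.train_labels,
                                  php.cls_forest)
    from .segmentation import segment_image  # local to avoid cycle at import

    dices, predicted = [], []
    for sample, stack in zip(data.val, data.val_stacks):
        pred_mask, _ = segment_image(segmenter, sample.image,
                                     feature_stack=stack)
        dices.append(dice(pred_mask, sample.mask))
        if not pred_mask.any():
            # keep the objective total: classify from the whole frame
            logger.info("empty predicted mask; falling back to full-image ABCD")
            pred_mask = np.ones_like(sample.mask, dtype=bool)
        fv = abcd_features(sample.image, pred_mask)
        predicted.append(classify_features(classifier, fv).label)
    mean_dice = float(np.mean(dices))
    bal_acc = balanced_accuracy(predicted, data.val_labels)
    loss = 1.0 - (weights.w_seg * mean_dice + weights.w_cls * bal_acc)
    return loss, mean_dice, bal_acc


def fitness_eval(
    position: Sequence[float],
    train_split: Sequence[SyntheticSample],
    val_split: Sequence[SyntheticSample],
    weights: FitnessWeights = FitnessWeights(),
    seed: int = 0,
    pixels_per_image: int = 200,
    _data: Optional[_PipelineData] = None,
) -> float:
    """Validation loss of the pipeline decoded from ``position`` (minimized)."""
    data = _data if _data is not None else _PipelineData(train_split, val_split)
    php = decode_position(position, seed=seed)
    loss, _, _ = _evaluate_hyperparams(php, data, weights, pixels_per_image)
    return loss


@dataclass
class TunedPipeline:
    segmenter: SegmenterModel
    classifier: object            # ForestModel
    hyperparams: PipelineHyperparams
    geo_result: GEOResult


def tune_pipeline(
    train_split: Sequence[SyntheticSample],
    val_split: Sequence[SyntheticSample],
    geo_config: GEOConfig,
    weights: FitnessWeights = FitnessWeights(),
    pixels_per_image: int = 200,
) -> TunedPipeline:
    """Run GEO over the hyperparameter space; retrain at the optimum.

    The final models are retrained on train+val at the best position found
    (with the default eagle guaranteeing no regression below the default
    configuration's validation fitness).
    """
    data = _PipelineData(train_split, val_split)
    space = pipeline_search_space()

    def objective(position: np.ndarray) -> float:
        return fitness_eval(position, train_split, val_split, weights,
                            seed=geo_config.seed,
                            pixels_per_image=pixels_per_image, _data=data)

    result = run_geo(space, geo_config, objective,
                     initial_positions=[encode_hyperparams(DEFAULT_HYPERPARAMS)])
    best = decode_position(result.best_position, seed=geo_config.seed)

    combined = list(train_split) + list(val_split)
    segmenter = train_segmenter(
        [s.image for s in combined], [s.mask for s in combined],
        best.seg_forest, best.seg_params,
        pixels_per_image=pixels_per_image,
        median_radius=data.median_radius,
        posterior_bias=best.posterior_bias,
        feature_stacks=data.train_stacks + data.val_stacks,
    )
    classifier = train_classifier(
        data.train_abcd + [abcd_features(s.image, s.mask) for s in val_split],
        data.train_labels + data.val_labels,
        best.cls_forest,
    )
    return TunedPipeline(segmenter=segmenter, classifier=classifier,
                         hyperparams=best, geo_result=result)


def train_default_pipeline(
    samples: Sequence[SyntheticSample],
    seed: int = 0,
    hyperparams: PipelineHyperparams = DEFAULT_HYPERPARAMS,
    pixels_per_image: int = 500,
) -> Tuple[SegmenterModel, object]:
    """Train segmenter + classifier at fixed hyperparameters on a dataset."""
    seg_hp = replace(hyperparams.seg_forest, seed=child_seed(seed, "forest", 0))
    cls_hp = replace(hyperparams.cls_forest, seed=child_seed(seed, "forest", 1))
    segmenter = train_segmenter(
        [s.image for s in samples], [s.mask for s in samples],
        seg_hp, hyperparams.seg_params,
        pixels_per_image=pixels_per_image,
        posterior_bias=hyperparams.posterior_bias,
    )
    classifier = train_classifier(
        [abcd_features(s.image, s.mask) for s in samples],
        [s.label for s in samples],
        cls_hp,
    )
    return segmenter, classifier
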