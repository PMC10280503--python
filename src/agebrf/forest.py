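"""Random-forest ensemble built from scratch.

The forest is the "numerous sub-trees" classification engine shared by the
pixel segmenter and the lesion classifier.  Trees are grown on bootstrap
resamples with per-split feature subsampling, splits chosen by exhaustive
Gini search over midpoints of sorted unique values, and predictions are the
mean of per-tree leaf class frequencies.  Everything is deterministic given
the hyperparameter seed, and models round-trip exactly through JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from ._tree_kernels import accumulate_leaf_freqs, grow_tree

_UNLIMITED_DEPTH = 10_000


@dataclass(frozen=True)
class ForestHyperparams:
    """Forest configuration.

    ``max_depth=None`` grows trees to purity.  ``feature_fraction`` is the
    fraction of features drawn (without replacement) as candidates at each
    split; the candidate count is ``ceil(feature_fraction * F)``.
    """

    n_trees: int = 30
    max_depth: Optional[int] = 12
    feature_fraction: float = 0.5
    min_samples_leaf: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if not (0.0 < self.feature_fraction <= 1.0):
            raise ValueError("feature_fraction must be in (0, 1]")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class _Tree:
    feature: np.ndarray   # int64, -1 for leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    counts: np.ndarray    # (n_nodes, n_classes) int64


@dataclass
class ForestModel:
    """Trained ensemble.

    ``posterior_bias`` is an additive offset applied to the positive-class
    posterior by the segmentation stage before thresholding; it defaults to
    0 and does not affect ``predict_proba``.
    """

    trees: List[_Tree]
    n_classes: int
    feature_count: int
    classes: List[int]
    posterior_bias: float = 0.0
    hyperparams: Optional[ForestHyperparams] = None

    def to_json(self) -> str:
        def node_record(tree: _Tree, i: int):
            if tree.feature[i] < 0:
                return {"counts": [int(c) for c in tree.counts[i]]}
            return {
                "feature": int(tree.feature[i]),
                "threshold": float(tree.threshold[i]),
                "left": node_record(tree, int(tree.left[i])),
                "right": node_record(tree, int(tree.right[i])),
                "counts": [int(c) for c in tree.counts[i]],
            }

        hp = None
        if self.hyperparams is not None:
            hp = {
                "n_trees": self.hyperparams.n_trees,
                "max_depth": self.hyperparams.max_depth,
                "feature_fraction": self.hyperparams.feature_fraction,
                "min_samples_leaf": self.hyperparams.min_samples_leaf,
                "seed": self.hyperparams.seed,
            }
        return json.dumps(
            {
                "n_classes": self.n_classes,
                "feature_count": self.feature_count,
                "classes": list(self.classes),
                "posterior_bias": float(self.posterior_bias),
                "hyperparams": hp,
                "trees": [node_record(t, 0) for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        d = json.loads(text)
        n_classes = int(d["n_classes"])

        def build(rec) -> _Tree:
            feat, thr, left, right, counts = [], [], [], [], []

            def walk(node) -> int:
                i = len(feat)
                feat.append(-1)
                thr.append(0.0)
                left.append(-1)
                right.append(-1)
                counts.append(node["counts"])
                if "feature" in node:
                    feat[i] = node["feature"]
                    thr[i] = node["threshold"]
                    left[i] = walk(node["left"])
                    right[i] = walk(node["right"])
                return i

            walk(rec)
            return _Tree(
                np.asarray(feat, np.int64),
                np.asarray(thr, float),
                np.asarray(left, np.int64),
                np.asarray(right, np.int64),
                np.asarray(counts, np.int64).reshape(len(feat), n_classes),
            )

        hp = None
        if d.get("hyperparams") is not None:
            hp = ForestHyperparams(**d["hyperparams"])
        return cls(
            trees=[build(r) for r in d["trees"]],
            n_classes=n_classes,
            feature_count=int(d["feature_count"]),
            classes=[int(c) for c in d["classes"]],
            posterior_bias=float(d["posterior_bias"]),
            hyperparams=hp,
        )


def _tree_seeds(seed: int, n_trees: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n_trees, dtype=np.uint64) % (2**31 - 1)).astype(np.int64)


def train_forest(features: np.ndarray, labels: Sequence[int],
                 hp: ForestHyperparams, bootstrap: bool = True) -> ForestModel:
    """Train a forest of ``hp.n_trees`` CART trees on bootstrap resamples."""
    X = np.ascontiguousarray(np.asarray(features, dtype=float))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be an N x F matrix with N >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    y_raw = np.asarray(labels)
    if y_raw.shape[0] != X.shape[0]:
        raise ValueError("labels length must match feature rows")
    classes = np.unique(y_raw)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    y = np.searchsorted(classes, y_raw).astype(np.int64)

    F = X.shape[1]
    mtry = int(math.ceil(hp.feature_fraction * F))
    mtry = min(max(mtry, 1), F)
    depth = _UNLIMITED_DEPTH if hp.max_depth is None else int(hp.max_depth)
    seeds = _tree_seeds(hp.seed, hp.n_trees)
    trees = []
    for s in seeds:
        arrays = grow_tree(X, y, int(classes.size), depth,
                           int(hp.min_samples_leaf), mtry, int(s), bootstrap)
        trees.append(_Tree(*arrays))
    return ForestModel(
        trees=trees,
        n_classes=int(classes.size),
        feature_count=F,
        classes=[int(c) for c in classes],
        hyperparams=hp,
    )


def predict_proba(model: ForestModel, features: np.ndarray) -> np.ndarray:
    """Posterior matrix: mean over trees of leaf class frequencies."""
    X = np.ascontiguousarray(np.asarray(features, dtype=float))
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.feature_count:
        raise ValueError(
            f"feature count mismatch: got {X.shape[1]}, model expects "
            f"{model.feature_count}"
        )
    out = np.zeros((X.shape[0], model.n_classes))
    for t in model.trees:
        accumulate_leaf_freqs(t.feature, t.threshold, t.left, t.right,
                              t.counts, X, out)
    out /= len(model.trees)
    return out


def predict_label(model: ForestModel, features: np.ndarray) -> np.ndarray:
    """Argmax of the posterior; ties resolve to the lower class index."""
    proba = predict_proba(model, features)
    idx = np.argmax(proba, axis=1)
    return np.asarray(model.classes)[idx]
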