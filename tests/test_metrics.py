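"""Confusion-matrix metrics, both modes, and mask overlap scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agebrf import metrics
from agebrf.metrics import ConfusionCounts


class TestConfusionConstruction:
    def test_all_malignant_correct(self):
        c = metrics.confusion_from_labels(["malignant"] * 4, ["malignant"] * 4)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 0, 0, 0)

    def test_all_benign_predictions_on_malignant_truth(self):
        c = metrics.confusion_from_labels(["benign"] * 3, ["malignant"] * 3)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 0, 3)

    def test_length_ten_case_by_enumeration(self):
        pred = ["malignant", "benign", "malignant", "benign", "malignant",
                "benign", "malignant", "benign", "benign", "malignant"]
        true = ["malignant", "malignant", "benign", "benign", "malignant",
                "benign", "benign", "malignant", "benign", "malignant"]
        c = metrics.confusion_from_labels(pred, true)
        # brute-force tally
        tp = sum(p == t == "malignant" for p, t in zip(pred, true))
        tn = sum(p == t == "benign" for p, t in zip(pred, true))
        fp = sum(p == "malignant" and t == "benign" for p, t in zip(pred, true))
        fn = sum(p == "benign" and t == "malignant" for p, t in zip(pred, true))
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_mask_confusion(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :2] = True          # predicted
        b[1, :2] = True          # truth, disjoint, equal area
        c = metrics.confusion_from_masks(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 2, 2, 12)
        identical = metrics.confusion_from_masks(b, b)
        assert identical.fp == identical.fn == 0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            metrics.confusion_from_labels(["benign"], ["benign", "benign"])


class TestScalarMetrics:
    def test_accuracy_direct(self):
        assert metrics.accuracy(ConfusionCounts(90, 5, 3, 2)) == 0.95
        assert metrics.accuracy(ConfusionCounts(0, 7, 0, 0)) == 1.0
        assert metrics.accuracy(ConfusionCounts(0, 0, 1, 1)) == 0.0

    def test_sensitivity_both_modes(self):
        assert metrics.sensitivity(ConfusionCounts(8, 0, 0, 2)) == 0.8
        # published-variant denominator tp + tn
        assert metrics.sensitivity(ConfusionCounts(8, 2, 0, 0),
                                   "paper_fidelity") == 0.8
        assert metrics.sensitivity(ConfusionCounts(5, 0, 3, 0)) == 1.0

    def test_specificity_both_modes(self):
        assert metrics.specificity(ConfusionCounts(0, 9, 1, 0)) == 0.9
        assert metrics.specificity(ConfusionCounts(1, 9, 0, 0),
                                   "paper_fidelity") == 0.9
        assert metrics.specificity(ConfusionCounts(5, 4, 0, 2)) == 1.0

    def test_precision(self):
        assert metrics.precision(ConfusionCounts(9, 0, 1, 0)) == 0.9
        assert metrics.precision(ConfusionCounts(3, 5, 0, 2)) == 1.0
        assert metrics.precision(ConfusionCounts(0, 0, 5, 0)) == 0.0

    def test_f1(self):
        assert metrics.f1_score(0.7, 0.7) == pytest.approx(0.7)
        assert metrics.f1_score(1.0, 0.5) == pytest.approx(2 / 3)
        # harmonic mean of a published precision/sensitivity pair
        assert metrics.f1_score(0.9929, 0.9934) == pytest.approx(0.99315, abs=5e-6)

    def test_zero_denominators_error_naming_mode(self):
        with pytest.raises(ValueError, match="standard"):
            metrics.sensitivity(ConfusionCounts(0, 3, 2, 0), "standard")
        with pytest.raises(ValueError, match="paper_fidelity"):
            metrics.sensitivity(ConfusionCounts(0, 0, 2, 3), "paper_fidelity")


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 500)] * 4).filter(lambda t: sum(t) > 0))
def test_confusion_identities(counts):
    tp, tn, fp, fn = counts
    c = ConfusionCounts(tp, tn, fp, fn)
    # exact integer identity
    assert metrics.accuracy(c) * c.total == pytest.approx(tp + tn, abs=1e-9)
    if tp + fn > 0:
        fnr = fn / (tp + fn)
        assert metrics.sensitivity(c) + fnr == pytest.approx(1.0)
    if tn + fp > 0:
        fpr = fp / (tn + fp)
        assert metrics.specificity(c) + fpr == pytest.approx(1.0)
    if tp + fp > 0 and tp + fn > 0 and tp > 0:
        p = metrics.precision(c)
        s = metrics.sensitivity(c)
        # harmonic mean never exceeds the geometric mean
        assert metrics.f1_score(p, s) <= np.sqrt(p * s) + 1e-12


class TestOverlapScores:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), dtype=bool)
        a[:4] = True
        b = ~a
        assert metrics.dice(a, a) == 1.0
        assert metrics.iou(a, a) == 1.0
        assert metrics.dice(a, b) == 0.0
        assert metrics.iou(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        e = np.zeros((4, 4), dtype=bool)
        assert metrics.dice(e, e) == 1.0
        assert metrics.iou(e, e) == 1.0

    def test_dice_iou_identity_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.uniform(size=(16, 16)) > 0.5
            b = rng.uniform(size=(16, 16)) > 0.5
            d = metrics.dice(a, b)
            j = metrics.iou(a, b)
            assert d == pytest.approx(2 * j / (1 + j))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            metrics.dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
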