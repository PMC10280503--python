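"""Synthetic dermoscopic generator: geometry, determinism, class separation."""

import numpy as np
import pandas as pd
import pytest

from agebrf._rng import substream
from agebrf.features import abcd_features
from agebrf.synthetic import (
    BENIGN,
    MALIGNANT,
    LesionGenParams,
    LesionGeometry,
    boundary_polygon,
    generate_dataset,
    generate_sample,
    generate_samples,
    radial_boundary,
)


@pytest.fixture(scope="module")
def class_samples():
    """50 samples per class with their ABCD feature vectors."""
    samples = generate_samples(50, 50, seed=404)
    feats = [abcd_features(s.image, s.mask) for s in samples]
    return samples, feats


class TestBoundary:
    def test_zero_harmonics_gives_a_circle(self):
        geom = LesionGeometry(center=(64.0, 64.0), r0=20.0,
                              amps=(0,) * 5, phases=(0,) * 5,
                              axis_ratio=1.0, orientation=0.0)
        poly = boundary_polygon(geom, 128)
        radii = np.hypot(poly[:, 0] - 64.0, poly[:, 1] - 64.0)
        np.testing.assert_allclose(radii, 20.0, atol=1e-9)
        assert poly.shape == (360, 2)

    def test_star_convexity_positive_radii(self):
        rng = np.random.default_rng(7)
        for label in (BENIGN, MALIGNANT):
            poly = radial_boundary(LesionGenParams(), rng, label)
            center = poly.mean(axis=0)
            radii = np.hypot(*(poly - center).T)
            assert np.all(radii > 0)

    def test_mean_vertex_radius_close_to_r0(self):
        # symmetric cosine modulation integrates to ~0 over a full turn
        geom = LesionGeometry(center=(64.0, 64.0), r0=18.0,
                              amps=(0.1, 0.08, 0.05, 0.12, 0.06),
                              phases=(0.3, 1.1, 2.9, 4.0, 5.5),
                              axis_ratio=1.0, orientation=0.0)
        poly = boundary_polygon(geom, 128)
        radii = np.hypot(poly[:, 0] - 64.0, poly[:, 1] - 64.0)
        assert abs(radii.mean() - 18.0) / 18.0 < 0.02


class TestGenerateSample:
    def test_bit_identical_for_same_seed(self):
        a = generate_sample(MALIGNANT, LesionGenParams(), np.random.default_rng(9))
        b = generate_sample(MALIGNANT, LesionGenParams(), np.random.default_rng(9))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_area_consistent_with_drawn_geometry(self):
        for i in range(10):
            s = generate_sample(BENIGN, LesionGenParams(),
                                substream(55, "generator", i))
            r0 = s.params_record["r0"]
            q = s.params_record["axis_ratio"]
            ellipse_area = np.pi * r0 ** 2 * q
            assert 0.5 * ellipse_area <= s.mask.sum() <= 1.6 * ellipse_area

    def test_masks_nonempty_and_aligned(self, class_samples):
        samples, _ = class_samples
        for s in samples:
            assert s.mask.any()
            assert s.mask.shape == s.image.shape[:2]


class TestClassSeparation:
    def test_asymmetry_medians_differ_between_classes(self, class_samples):
        _, feats = class_samples
        benign = np.median([f.asymmetry for f in feats[:50]])
        malignant = np.median([f.asymmetry for f in feats[50:]])
        assert malignant - benign > 0.05

    def test_shallow_tree_separates_classes(self, class_samples):
        # a depth-3 tree on ABCD features must reach 85% 5-fold accuracy,
        # which guarantees the downstream classifier has signal to learn
        from sklearn.model_selection import cross_val_score
        from sklearn.tree import DecisionTreeClassifier

        samples, feats = class_samples
        X = np.vstack([f.to_array() for f in feats])
        y = np.array([s.label == MALIGNANT for s in samples], dtype=int)
        scores = cross_val_score(DecisionTreeClassifier(max_depth=3,
                                                        random_state=0),
                                 X, y, cv=5)
        assert scores.mean() >= 0.85

    def test_separation_scalar_shrinks_class_gaps(self):
        hard = LesionGenParams(separation=0.0)
        assert hard.radius_range(BENIGN) == hard.radius_range(MALIGNANT)
        easy = LesionGenParams(separation=1.0)
        assert easy.radius_range(BENIGN) == easy.base_radius_frac_benign


class TestGenerateDataset:
    def test_writes_counts_and_manifest(self, tmp_path):
        manifest = generate_dataset(3, 2, tmp_path / "d",
                                    params=LesionGenParams(image_size=32),
                                    seed=1)
        assert len(manifest) == 5
        assert list(manifest["label"]) == [BENIGN] * 3 + [MALIGNANT] * 2
        assert len(list((tmp_path / "d" / "images").glob("*.png"))) == 5
        assert len(list((tmp_path / "d" / "masks").glob("*.png"))) == 5
        again = pd.read_csv(tmp_path / "d" / "manifest.csv")
        assert list(again.columns) == ["id", "label", "seed", "params"]

    def test_empty_dataset(self, tmp_path):
        manifest = generate_dataset(0, 0, tmp_path / "e", seed=0)
        assert len(manifest) == 0
        assert not (tmp_path / "e" / "images").exists()

    def test_round_trip_through_png(self, tmp_path):
        from agebrf.cli import load_dataset

        generate_dataset(2, 1, tmp_path / "rt",
                         params=LesionGenParams(image_size=48), seed=3)
        loaded = load_dataset(tmp_path / "rt")
        fresh = generate_samples(2, 1, LesionGenParams(image_size=48), seed=3)
        for a, b in zip(loaded, fresh):
            np.testing.assert_array_equal(a.image, b.image)
            np.testing.assert_array_equal(a.mask, b.mask)
            assert a.label == b.label
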