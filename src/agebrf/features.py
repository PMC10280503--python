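"""Lesion-level ABCD features: Asymmetry, Border, Color, Diameter.

Given an RGB image and a binary lesion mask the extractor computes the
clinical ABCD descriptors used for benign/malignant classification:

* asymmetry — mean, over the two principal axes of the mask (from its
  second moments), of the area that fails to overlap itself after
  reflection about the axis, normalized by twice the lesion area (0 =
  perfectly mirror-symmetric, 1 = no overlap at all);
* border irregularity — the isoperimetric quotient P^2 / (4 pi A), >= 1
  with equality for a disk; the perimeter P is the Crofton estimate from
  4 projection directions;
* color — per-channel mean and standard deviation of the pixels inside
  the mask, on a [0, 1] intensity scale;
* diameter — the maximum Feret (caliper) diameter of the mask, computed
  exactly from the convex hull of the boundary pixels' corners, as a
  fraction of the image diagonal; plus the lesion area as a fraction of
  the image area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import perimeter_crofton

from .preprocessing import validate_rgb_image

LesionMask = np.ndarray  # bool, H x W

FEATURE_COLUMNS: List[str] = [
    "asymmetry", "border_irregularity",
    "color_mean_r", "color_mean_g", "color_mean_b",
    "color_std_r", "color_std_g", "color_std_b",
    "diameter_frac", "area_frac",
]


def validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValueError("mask values must be binary (0/1 or 0/255)")
        mask = mask > 0
    return mask


def mask_area(mask: LesionMask) -> int:
    return int(np.count_nonzero(validate_mask(mask)))


@dataclass(frozen=True)
class LesionFeatureVector:
    asymmetry: float
    border_irregularity: float
    color_means: tuple
    color_stds: tuple
    diameter_frac: float
    area_frac: float

    def to_array(self) -> np.ndarray:
        """Flatten to the documented 10-column order (``FEATURE_COLUMNS``)."""
        return np.array([
            self.asymmetry, self.border_irregularity,
            *self.color_means, *self.color_stds,
            self.diameter_frac, self.area_frac,
        ])


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Eigenvectors (rows) of the coordinate covariance, major axis first."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, ::-1].T  # rows: major, minor


def _reflection_mismatch(proj: np.ndarray, flip_axis: int) -> float:
    """Non-overlap fraction between a rounded point set and its reflection."""
    pts = np.rint(proj).astype(np.int64)
    refl = proj.copy()
    refl[:, flip_axis] = -refl[:, flip_axis]
    rpts = np.rint(refl).astype(np.int64)
    a = {tuple(p) for p in pts}
    b = {tuple(p) for p in rpts}
    return len(a.symmetric_difference(b)) / (2.0 * len(a))


def mask_asymmetry(mask: LesionMask) -> float:
    """Mean reflection mismatch about the two principal axes, in [0, 1]."""
    mask = validate_mask(mask)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    axes = _principal_axes(coords)
    centered = coords - coords.mean(axis=0)
    proj = centered @ axes.T  # coordinates in the principal frame
    return 0.5 * (_reflection_mismatch(proj, 1) + _reflection_mismatch(proj, 0))


def feret_diameter(mask: LesionMask) -> float:
    """Maximum caliper distance, from the hull of boundary-pixel corners."""
    mask = validate_mask(mask)
    if not mask.any():
        raise ValueError("empty mask")
    eroded = ndimage.binary_erosion(mask, border_value=0)
    boundary = np.argwhere(mask & ~eroded).astype(float)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (boundary[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    corners = np.unique(corners, axis=0)
    hull_pts = corners[ConvexHull(corners).vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def abcd_features(image: np.ndarray, mask: LesionMask) -> LesionFeatureVector:
    """ABCD descriptor vector of a masked lesion (deterministic)."""
    image = validate_rgb_image(image)
    mask = validate_mask(mask)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image")
    area = int(np.count_nonzero(mask))
    if area == 0:
        raise ValueError("empty mask: no lesion pixels")

    asym = mask_asymmetry(mask)

    perim = perimeter_crofton(mask, directions=4)
    border = float(perim * perim / (4.0 * np.pi * area))

    inside = image[mask].astype(float) / 255.0
    means = tuple(float(v) for v in inside.mean(axis=0))
    stds = tuple(float(v) for v in inside.std(axis=0))

    H, W = mask.shape
    diam = feret_diameter(mask) / float(np.hypot(H, W))

    return LesionFeatureVector(
        asymmetry=float(asym),
        border_irregularity=border,
        color_means=means,
        color_stds=stds,
        diameter_frac=float(diam),
        area_frac=area / float(H * W),
    )
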