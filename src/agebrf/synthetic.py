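"""Synthetic dermoscopic-image generator with exact ground truth.

Each sample is a skin-toned background (Gaussian pixel noise plus a smooth
illumination gradient) carrying a single star-convex pigmented lesion whose
boundary is a radial harmonic curve

    r(theta) = r0 * s(theta) * (1 + sum_{k=2..6} a_k cos(k theta + phi_k))

with ``s`` an elliptical scaling.  Class-conditional parameter ranges make
benign and malignant lesions differ in the ABCD sense: malignant lesions
are larger (Diameter), more elongated and with random-phase harmonics
(Asymmetry), more wiggly-edged (Border) and carry extra pigment patches
(Color variegation).  The ground-truth mask is the exact polygon
rasterization *before* the photometric border blend, so truth is geometric.

A ``separation`` scalar in [0, 1] shrinks every class-conditional range
toward its benign/malignant midpoint: 1 keeps the documented (well
separated) defaults, 0 collapses the classes onto a common distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from ._rng import substream

Range = Tuple[float, float]

BENIGN, MALIGNANT = "benign", "malignant"

# overlay pigments for malignant color variegation
_PATCH_PALETTE = np.array([
    [60, 35, 25],    # dark brown
    [80, 85, 110],   # blue-grey
    [160, 60, 55],   # red
    [35, 25, 20],    # near-black
], dtype=float)


@dataclass(frozen=True)
class LesionGenParams:
    image_size: int = 128
    base_radius_frac_benign: Range = (0.10, 0.18)
    base_radius_frac_malignant: Range = (0.16, 0.28)
    harmonic_amps_benign: Range = (0.0, 0.05)
    harmonic_amps_malignant: Range = (0.08, 0.25)
    ellipticity_benign: Range = (0.85, 1.0)
    ellipticity_malignant: Range = (0.55, 0.9)
    n_color_patches_benign: Tuple[int, int] = (0, 1)
    n_color_patches_malignant: Tuple[int, int] = (2, 5)
    skin_tone: Tuple[int, int, int] = (225, 185, 160)
    noise_sigma: float = 6.0
    illumination: float = 0.10
    hair: bool = False
    separation: float = 1.0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0.0 <= self.separation <= 1.0):
            raise ValueError("separation must be in [0, 1]")

    def _scaled(self, benign: Range, malignant: Range, label: str) -> Range:
        mid = (benign[0] + benign[1] + malignant[0] + malignant[1]) / 4.0
        lo, hi = benign if label == BENIGN else malignant
        s = self.separation
        return (mid + s * (lo - mid), mid + s * (hi - mid))

    def radius_range(self, label: str) -> Range:
        return self._scaled(self.base_radius_frac_benign,
                            self.base_radius_frac_malignant, label)

    def amp_range(self, label: str) -> Range:
        return self._scaled(self.harmonic_amps_benign,
                            self.harmonic_amps_malignant, label)

    def ellipticity_range(self, label: str) -> Range:
        return self._scaled(self.ellipticity_benign,
                            self.ellipticity_malignant, label)

    def patch_range(self, label: str) -> Tuple[int, int]:
        lo, hi = self._scaled(
            tuple(map(float, self.n_color_patches_benign)),
            tuple(map(float, self.n_color_patches_malignant)), label)
        return (int(round(lo)), int(round(hi)))


@dataclass(frozen=True)
class LesionGeometry:
    """Drawn shape parameters for one lesion."""

    center: Tuple[float, float]       # (row, col)
    r0: float                         # base radius, pixels
    amps: Tuple[float, ...]           # harmonic amplitudes, k = 2..6
    phases: Tuple[float, ...]
    axis_ratio: float                 # minor/major, in (0, 1]
    orientation: float                # radians


@dataclass
class SyntheticSample:
    image: np.ndarray                 # uint8 H x W x 3
    mask: np.ndarray                  # bool H x W
    label: str
    params_record: dict


def sample_geometry(label: str, params: LesionGenParams,
                    rng: np.random.Generator) -> LesionGeometry:
    size = params.image_size
    r_lo, r_hi = params.radius_range(label)
    a_lo, a_hi = params.amp_range(label)
    e_lo, e_hi = params.ellipticity_range(label)
    center = (size / 2.0 + rng.uniform(-0.1, 0.1) * size,
              size / 2.0 + rng.uniform(-0.1, 0.1) * size)
    return LesionGeometry(
        center=center,
        r0=float(rng.uniform(r_lo, r_hi) * size),
        amps=tuple(rng.uniform(a_lo, a_hi, 5)),
        phases=tuple(rng.uniform(0.0, 2.0 * np.pi, 5)),
        axis_ratio=float(rng.uniform(e_lo, e_hi)),
        orientation=float(rng.uniform(0.0, np.pi)),
    )


def boundary_polygon(geom: LesionGeometry, image_size: int,
                     n_vertices: int = 360, margin: float = 4.0) -> np.ndarray:
    """Star-convex boundary polygon, (n_vertices, 2) array of (row, col).

    Radii are clipped so every vertex stays at least ``margin`` pixels from
    the image edge (and at least 2 px from the center), which keeps the
    rasterized mask fully inside the frame.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    u = theta - geom.orientation
    q = geom.axis_ratio
    s = 1.0 / np.sqrt(np.cos(u) ** 2 + (np.sin(u) / q) ** 2)
    mod = np.ones_like(theta)
    for k, (a, phi) in enumerate(zip(geom.amps, geom.phases), start=2):
        mod += a * np.cos(k * theta + phi)
    r = geom.r0 * s * np.clip(mod, 0.05, None)

    cy, cx = geom.center
    dy, dx = np.sin(theta), np.cos(theta)
    lo, hi = margin, image_size - 1.0 - margin
    t_edge = np.full_like(theta, np.inf)
    for d, c in ((dy, cy), (dx, cx)):
        with np.errstate(divide="ignore"):
            t1 = np.where(d > 1e-12, (hi - c) / np.where(d == 0, 1, d), np.inf)
            t2 = np.where(d < -1e-12, (lo - c) / np.where(d == 0, 1, d), np.inf)
        t_edge = np.minimum(t_edge, np.minimum(t1, t2))
    r = np.clip(r, 2.0, t_edge)
    return np.column_stack([cy + r * dy, cx + r * dx])


def radial_boundary(params: LesionGenParams, rng: np.random.Generator,
                    label: str = BENIGN) -> np.ndarray:
    """Draw a class-conditional lesion geometry and return its polygon."""
    geom = sample_geometry(label, params, rng)
    return boundary_polygon(geom, params.image_size)


def _rasterize(poly: np.ndarray, size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(size, size))
    mask[rr, cc] = True
    return mask


def generate_sample(label: str, params: LesionGenParams,
                    rng: np.random.Generator) -> SyntheticSample:
    """Render one image/mask/label triple (deterministic given the rng)."""
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"unknown label {label!r}")
    size = params.image_size
    geom = sample_geometry(label, params, rng)
    poly = boundary_polygon(geom, size)
    mask = _rasterize(poly, size)

    # background: skin tone + smooth illumination ramp + pixel noise
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    ramp = ((yy - size / 2) * np.sin(phi) + (xx - size / 2) * np.cos(phi))
    ramp = 1.0 + params.illumination * ramp / (size / 2 * np.sqrt(2))
    background = np.asarray(params.skin_tone, float)[None, None, :] * ramp[:, :, None]

    # lesion pigment layer
    if label == BENIGN:
        pigment = np.array([120.0, 80.0, 60.0]) + rng.uniform(-10, 10, 3)
    else:
        pigment = np.array([95.0, 60.0, 45.0]) + rng.uniform(-15, 15, 3)
    lesion_layer = np.broadcast_to(pigment, (size, size, 3)).copy()

    p_lo, p_hi = params.patch_range(label)
    n_patches = int(rng.integers(p_lo, p_hi + 1)) if p_hi >= p_lo else 0
    patch_records = []
    lesion_px = np.argwhere(mask)
    for _ in range(n_patches):
        color = _PATCH_PALETTE[rng.integers(len(_PATCH_PALETTE))]
        py, px = lesion_px[rng.integers(len(lesion_px))]
        prad = rng.uniform(0.15, 0.35) * geom.r0
        blob = (yy - py) ** 2 + (xx - px) ** 2 <= prad ** 2
        lesion_layer[blob & mask] = color + rng.uniform(-8, 8, 3)
        patch_records.append({"center": [int(py), int(px)],
                              "radius": float(prad),
                              "color": [float(c) for c in color]})

    alpha = ndimage.gaussian_filter(mask.astype(float), sigma=2.0)[:, :, None]
    img = alpha * lesion_layer + (1.0 - alpha) * background
    img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    record = {
        "label": label,
        "center": [float(geom.center[0]), float(geom.center[1])],
        "r0": geom.r0,
        "amps": [float(a) for a in geom.amps],
        "phases": [float(p) for p in geom.phases],
        "axis_ratio": geom.axis_ratio,
        "orientation": geom.orientation,
        "pigment": [float(c) for c in pigment],
        "patches": patch_records,
    }
    return SyntheticSample(image=image, mask=mask, label=label,
                           params_record=record)


def generate_samples(n_benign: int, n_malignant: int,
                     params: Optional[LesionGenParams] = None,
                     seed: int = 0) -> List[SyntheticSample]:
    """In-memory dataset: benign samples first, then malignant."""
    params = params or LesionGenParams()
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    return [
        generate_sample(label, params, substream(seed, "generator", i))
        for i, label in enumerate(labels)
    ]


def generate_dataset(n_benign: int, n_malignant: int, out_dir,
                     params: Optional[LesionGenParams] = None,
                     seed: int = 0) -> pd.DataFrame:
    """Write images/, masks/ PNGs and manifest.csv; return the manifest."""
    from .pngio import save_image, save_mask

    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be >= 0")
    params = params or LesionGenParams()
    out_dir = Path(out_dir)
    rows = []
    samples = generate_samples(n_benign, n_malignant, params, seed)
    if samples:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    else:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, sample in enumerate(samples):
        sid = f"sample_{i:05d}"
        save_image(out_dir / "images" / f"{sid}.png", sample.image)
        save_mask(out_dir / "masks" / f"{sid}.png", sample.mask)
        rows.append({
            "id": sid,
            "label": sample.label,
            "seed": seed,
            "params": json.dumps(sample.params_record, sort_keys=True),
        })
    manifest = pd.DataFrame(rows, columns=["id", "label", "seed", "params"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
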