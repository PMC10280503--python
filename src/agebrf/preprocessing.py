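"""Image preprocessing and per-pixel feature extraction.

Images are plain ``uint8`` H x W x 3 arrays (``RGBImage`` alias) and lesion
masks are boolean H x W arrays; the helpers here validate shapes and ranges
at the API boundary.  Preprocessing is a per-channel median filter followed
by a robust (1st/99th percentile) contrast stretch.  The per-pixel feature
stack is a fixed 12-plane nonlinear filter bank covering color (RGB + HSV),
local texture (windowed mean/std of the gray image at two scales), edges
(gradient magnitude of the Gaussian-smoothed gray image) and geometry
(normalized distance from the image center) — the shape/color/size/texture
vocabulary the downstream pixel classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv

RGBImage = np.ndarray  # uint8, H x W x 3

MIN_IMAGE_SIDE = 32

PIXEL_FEATURE_NAMES: List[str] = [
    "r", "g", "b",
    "hue", "saturation", "value",
    "local_mean_5", "local_std_5",
    "local_mean_11", "local_std_11",
    "grad_mag",
    "center_dist",
]

KERNEL_SET: Dict[str, object] = {
    "windows": [5, 11],
    "padding": "reflect",
    "gaussian_sigma": 1.0,
    "gradient": "central_differences",
}


def validate_rgb_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    if image.shape[0] < MIN_IMAGE_SIDE or image.shape[1] < MIN_IMAGE_SIDE:
        raise ValueError(f"image sides must be >= {MIN_IMAGE_SIDE}")
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        image = image.astype(np.uint8)
    return image


def preprocess(image: RGBImage, median_radius: int = 1) -> RGBImage:
    """Denoise and contrast-stretch a dermoscopic frame.

    Each channel is median-filtered with a (2r+1) x (2r+1) window (radius 0
    is the identity), then linearly stretched so its 1st/99th intensity
    percentiles map to 0/255, with clipping.  A channel whose percentiles
    coincide (constant channel) is left unstretched.
    """
    image = validate_rgb_image(image)
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    if median_radius > min(image.shape[0], image.shape[1]) // 2:
        raise ValueError("median_radius larger than half the smallest image side")
    out = np.empty_like(image, dtype=float)
    for c in range(3):
        chan = image[:, :, c].astype(float)
        if median_radius > 0:
            chan = ndimage.median_filter(
                chan, size=2 * median_radius + 1, mode="reflect"
            )
        p1, p99 = np.percentile(chan, [1.0, 99.0])
        if p99 > p1:
            chan = (chan - p1) * (255.0 / (p99 - p1))
        out[:, :, c] = chan
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class PixelFeatureStack:
    """Per-pixel feature planes (H x W x F) plus plane labels."""

    planes: np.ndarray
    feature_names: List[str] = field(default_factory=lambda: list(PIXEL_FEATURE_NAMES))
    kernel_set: Dict[str, object] = field(default_factory=lambda: dict(KERNEL_SET))

    def __post_init__(self):
        if self.planes.shape[2] != len(self.feature_names):
            raise ValueError("plane count does not match feature_names")

    @property
    def matrix(self) -> np.ndarray:
        """Flattened (H*W) x F feature matrix in row-major pixel order."""
        return self.planes.reshape(-1, self.planes.shape[2])


def _local_stats(gray: np.ndarray, size: int):
    m1 = ndimage.uniform_filter(gray, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(gray * gray, size=size, mode="reflect")
    return m1, np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))


def pixel_features(image: RGBImage) -> PixelFeatureStack:
    """Extract the 12-plane per-pixel feature stack (deterministic)."""
    image = validate_rgb_image(image)
    H, W = image.shape[:2]
    rgb = image.astype(float) / 255.0
    hsv = rgb2hsv(rgb)
    gray = rgb2gray(rgb)

    mean5, std5 = _local_stats(gray, 5)
    mean11, std11 = _local_stats(gray, 11)

    smooth = ndimage.gaussian_filter(gray, sigma=1.0, mode="reflect")
    gy, gx = np.gradient(smooth)
    grad = np.hypot(gy, gx)

    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    dist = np.hypot(rr - cy, cc - cx)
    dist /= np.hypot(cy, cx)  # corner pixel -> 1

    planes = np.dstack([
        rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2],
        hsv[:, :, 0], hsv[:, :, 1], hsv[:, :, 2],
        mean5, std5, mean11, std11,
        grad,
        dist,
    ])
    if not np.all(np.isfinite(planes)):
        raise ValueError("non-finite feature plane values")
    return PixelFeatureStack(planes)
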