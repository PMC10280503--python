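"""PNG I/O: 8-bit RGB images, 0/255 binary masks, 16-bit posterior maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB PNG as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(path, image: np.ndarray) -> None:
    image = np.asarray(image, dtype=np.uint8)
    Image.fromarray(image, mode="RGB").save(Path(path))


def load_mask(path) -> np.ndarray:
    """Read a 0/255 single-channel PNG as a boolean mask."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def save_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(Path(path))


def save_posterior(path, posterior: np.ndarray) -> None:
    """Write a [0, 1] posterior map as a 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(posterior, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535.0).round().astype(np.uint16)).save(Path(path))


def load_posterior(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.float64) / 65535.0
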