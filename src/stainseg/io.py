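"""Image and mask I/O.

Images are PNG or TIFF, 8- or 16-bit per channel, decoded to float64
intensities in [0, 1].  Label masks are single-channel 8-bit PNGs with the
palette 0 = unlabeled, 1 = hematoxylin, 2 = DAB, 3 = lumen.  Posterior maps
are written as 16-bit grayscale PNGs next to a JSON stack manifest.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidInputError


def load_rgb_image(path: str | Path) -> np.ndarray:
    """Load an RGB image as an H x W x 3 float64 array in [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raise InvalidInputError(f"{path}: expected an RGB image, got one channel")
    if raw.ndim != 3:
        raise InvalidInputError(f"{path}: unsupported image layout {raw.shape}")
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.shape[2] != 3:
        raise InvalidInputError(f"{path}: expected 3 channels, got {raw.shape[2]}")
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    arr = raw.astype(np.float64)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidInputError(f"{path}: float image values must lie in [0, 1]")
    return arr


def save_rgb_image(path: str | Path, img: np.ndarray) -> None:
    """Write an H x W x 3 float array in [0, 1] as an 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (np.round(arr * 255.0)).astype(np.uint8))


def load_label_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel label mask (uint8)."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return raw.astype(np.uint8)


def save_label_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(mask, dtype=np.uint8))


def save_posterior_map(path: str | Path, pmap: np.ndarray) -> None:
    """Write a posterior map in [0, 1] as a 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(pmap, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))


def load_posterior_map(path: str | Path) -> np.ndarray:
    raw = iio.imread(path)
    if raw.dtype != np.uint16:
        raise InvalidInputError(f"{path}: posterior maps are stored as 16-bit PNGs")
    return raw.astype(np.float64) / 65535.0
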