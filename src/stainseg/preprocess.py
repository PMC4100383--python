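"""Image preprocessing and the stain feature space.

A raw RGB image is downscaled with bicubic interpolation, smoothed with a
per-channel Gaussian low-pass filter, and its pixels are treated as points
in the 3-D RGB feature space.  That space is normalized per channel to
[0, 1], rotated with PCA so the first axis follows the direction of maximum
variance (no dimension is dropped), and optionally rescaled per rotated
axis before clustering.  The normalization bounds, rotation and scale
weights together form a :class:`StainSpaceModel` that can be fitted on one
pixel set and applied to another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .config import PipelineConfig
from .exceptions import DegenerateDataError, InvalidInputError

#: Gaussian kernels are truncated at this many standard deviations.
GAUSSIAN_TRUNCATE = 4.0


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a nonempty H x W x 3 float array in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected an H x W x 3 image, got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise InvalidInputError("empty image")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidInputError("image intensities must lie in [0, 1]")
    return arr


def preprocess_image(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Downscale (bicubic) and Gaussian-smooth each channel independently.

    The output size is ``round(dimension * factor)`` with a floor of 1.
    Smoothing uses reflective boundaries so tissue touching the border is
    not darkened.  Values are clipped back to [0, 1].
    """
    arr = validate_rgb(img)
    h, w = arr.shape[:2]
    out_h = max(1, int(round(h * cfg.downscale_factor)))
    out_w = max(1, int(round(w * cfg.downscale_factor)))
    if (out_h, out_w) != (h, w):
        arr = resize(
            arr,
            (out_h, out_w),
            order=3,
            mode="reflect",
            anti_aliasing=False,
            preserve_range=True,
        )
    if cfg.gaussian_sigma > 0:
        arr = gaussian_filter(
            arr,
            sigma=(cfg.gaussian_sigma, cfg.gaussian_sigma, 0.0),
            mode="reflect",
            truncate=GAUSSIAN_TRUNCATE,
        )
    return np.clip(arr, 0.0, 1.0)


def image_to_features(img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Flatten an image to an N x 3 row-major (raster order) feature matrix.

    Returns the rows and the ``(H, W)`` shape needed to reshape back.
    """
    arr = validate_rgb(img)
    h, w = arr.shape[:2]
    return arr.reshape(h * w, 3), (h, w)


def features_to_image(rows: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`image_to_features`."""
    rows = np.asarray(rows, dtype=np.float64)
    h, w = shape
    if rows.shape != (h * w, 3):
        raise InvalidInputError(
            f"cannot reshape {rows.shape} rows into a {h}x{w}x3 image"
        )
    return rows.reshape(h, w, 3)


@dataclass(frozen=True)
class StainSpaceModel:
    """Per-channel normalization bounds plus a PCA rotation and axis weights.

    ``rotation`` holds the principal axes as columns, ordered by decreasing
    eigenvalue of the covariance of the normalized features; each axis sign
    is fixed so its largest-magnitude coefficient is positive.
    """

    channel_min: np.ndarray
    channel_max: np.ndarray
    mean: np.ndarray
    rotation: np.ndarray
    scale_weights: np.ndarray = field(
        default_factory=lambda: np.ones(3, dtype=np.float64)
    )

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        if r.shape != (3, 3) or not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise InvalidInputError("rotation must be 3x3 orthonormal (tol 1e-8)")
        if np.any(np.asarray(self.scale_weights) <= 0):
            raise InvalidInputError("scale_weights must be positive")


def _fix_eigvec_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude coefficient is positive."""
    vecs = vecs.copy()
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def fit_stain_space(
    features: np.ndarray,
    scale_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> StainSpaceModel:
    """Fit normalization bounds and the PCA rotation on a pixel set.

    The rotation's columns are the eigenvectors of the covariance of the
    normalized features, in decreasing-eigenvalue order; all three
    components are retained (no reduction).
    """
    rows = np.asarray(features, dtype=np.float64)
    if rows.ndim != 2 or rows.shape[1] != 3:
        raise InvalidInputError("features must be N x 3")
    if np.unique(rows, axis=0).shape[0] < 2:
        raise DegenerateDataError("need at least 2 distinct pixel colors")
    cmin = rows.min(axis=0)
    cmax = rows.max(axis=0)
    model0 = StainSpaceModel(
        channel_min=cmin,
        channel_max=cmax,
        mean=np.zeros(3),
        rotation=np.eye(3),
        scale_weights=np.asarray(scale_weights, dtype=np.float64),
    )
    norm = normalize_features(rows, model0)
    mean = norm.mean(axis=0)
    cov = np.cov(norm, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]  # decreasing variance
    evecs = _fix_eigvec_signs(evecs[:, order])
    return StainSpaceModel(
        channel_min=cmin,
        channel_max=cmax,
        mean=mean,
        rotation=evecs,
        scale_weights=np.asarray(scale_weights, dtype=np.float64),
    )


def normalize_features(features: np.ndarray, model: StainSpaceModel) -> np.ndarray:
    """Affinely map each channel so channel_min -> 0 and channel_max -> 1.

    Constant channels map to 0; values outside the fitted bounds clip to
    [0, 1].
    """
    rows = np.asarray(features, dtype=np.float64)
    if rows.ndim != 2 or rows.shape[1] != 3:
        raise InvalidInputError("features must be N x 3")
    span = np.asarray(model.channel_max) - np.asarray(model.channel_min)
    out = np.zeros_like(rows)
    nz = span > 0
    out[:, nz] = (rows[:, nz] - np.asarray(model.channel_min)[nz]) / span[nz]
    return np.clip(out, 0.0, 1.0)


def transform_features(features: np.ndarray, model: StainSpaceModel) -> np.ndarray:
    """Center, rotate onto the principal axes, and rescale per axis.

    Expects features already normalized by the same model.  With unit scale
    weights this is an isometry; with all weights positive it is invertible.
    """
    rows = np.asarray(features, dtype=np.float64)
    if rows.ndim != 2 or rows.shape[1] != 3:
        raise InvalidInputError("features must be N x 3")
    return ((rows - np.asarray(model.mean)) @ np.asarray(model.rotation)) * np.asarray(
        model.scale_weights
    )


def stain_space_transform(
    features: np.ndarray, model: StainSpaceModel
) -> np.ndarray:
    """Normalize then transform in one call (the clustering feature space)."""
    return transform_features(normalize_features(features, model), model)
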