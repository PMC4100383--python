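"""Fuzzy clustering of non-DAB pixels and posterior-map handling.

Non-DAB pixels are clustered in the stain feature space with fuzzy k-means
(k = 3 by default, fuzzifier m = 2).  The soft memberships are scattered
back onto the image grid as posterior probability maps, the maps are sorted
ascending by posterior-weighted mean grayscale intensity (darkest class —
nuclei — first), the DAB detection is reinserted as a crisp fourth map, and
class area fractions are read off with the maximum-a-posteriori rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    ConsistencyError,
    DegenerateDataError,
    InvalidInputError,
)
from .labels import CLUSTER_NAMES_BY_INTENSITY


@dataclass(frozen=True)
class FuzzyClustering:
    centers: np.ndarray  # k x d
    memberships: np.ndarray  # N x k, rows sum to 1
    objective_history: list[float]
    iterations: int
    seed: int


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)).

    A point coinciding with a center gets membership 1 there (0 elsewhere);
    coinciding with several centers, the membership is split evenly.
    """
    exp = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-exp)
    zero_rows = ~np.all(np.isfinite(inv), axis=1)
    u = np.empty_like(d2)
    ok = ~zero_rows
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        hits = d2[zero_rows] == 0.0
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return u


def _fcm_objective(d2: np.ndarray, u: np.ndarray, m: float) -> float:
    return float(np.sum((u**m) * d2))


def fuzzy_kmeans(
    features: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means by alternating membership/center updates.

    Centers are initialized as ``k`` distinct data points drawn with the
    seed.  Iteration stops when the maximum absolute membership change
    drops below ``tol`` or after ``max_iter`` sweeps; the objective
    ``sum(u^m * d^2)`` is recorded every sweep and is non-increasing.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InvalidInputError("features must be N x d")
    n = x.shape[0]
    if m <= 1:
        raise InvalidInputError("fuzzifier m must be > 1")
    if n < k:
        raise InvalidInputError(f"need at least k={k} points, got {n}")
    uniq = np.unique(x, axis=0)
    if uniq.shape[0] == 1:
        raise DegenerateDataError("all points identical; nothing to cluster")
    if uniq.shape[0] < k:
        raise DegenerateDataError(
            f"only {uniq.shape[0]} distinct points for k={k} clusters"
        )
    rng = np.random.default_rng(seed)
    centers = uniq[rng.choice(uniq.shape[0], size=k, replace=False)].copy()

    u = None
    history: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d2 = cdist(x, centers, metric="sqeuclidean")
        u_new = _fcm_memberships(d2, m)
        history.append(_fcm_objective(d2, u_new, m))
        if u is not None and float(np.max(np.abs(u_new - u))) < tol:
            u = u_new
            break
        u = u_new
        um = u**m
        denom = um.sum(axis=0)
        # a cluster can lose all support only in pathological ties; keep its
        # center where it was in that case
        nz = denom > 0
        centers[nz] = (um.T @ x)[nz] / denom[nz, None]
    return FuzzyClustering(
        centers=centers,
        memberships=u,
        objective_history=history,
        iterations=iterations,
        seed=seed,
    )


@dataclass(frozen=True)
class PosteriorMapStack:
    """k (or k+1 with DAB) aligned posterior maps; per-pixel sums are 1
    wherever any map is supported."""

    maps: np.ndarray  # C x H x W
    class_names: tuple[str, ...]
    order_key: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=np.float64)
        if m.ndim != 3 or m.shape[0] != len(self.class_names):
            raise InvalidInputError("maps must be C x H x W with C class names")
        if m.min() < -1e-9 or m.max() > 1.0 + 1e-9:
            raise InvalidInputError("posterior values must lie in [0, 1]")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


def memberships_to_maps(
    clustering: FuzzyClustering,
    non_dab_index: np.ndarray,
    shape: tuple[int, int],
) -> PosteriorMapStack:
    """Scatter cluster memberships back to image coordinates.

    ``non_dab_index`` holds the flat (row-major) pixel indices that were
    clustered; all other pixels carry 0 in every map at this stage.
    """
    h, w = shape
    idx = np.asarray(non_dab_index, dtype=np.int64)
    u = np.asarray(clustering.memberships)
    if idx.shape[0] != u.shape[0]:
        raise InvalidInputError("index list must address exactly the clustered pixels")
    if idx.size and (idx.min() < 0 or idx.max() >= h * w):
        raise InvalidInputError("pixel index out of range")
    k = u.shape[1]
    maps = np.zeros((k, h * w))
    maps[:, idx] = u.T
    return PosteriorMapStack(
        maps=maps.reshape(k, h, w),
        class_names=tuple(f"cluster{i}" for i in range(k)),
    )


def order_maps(stack: PosteriorMapStack, gray: np.ndarray) -> PosteriorMapStack:
    """Sort maps ascending by posterior-weighted mean grayscale intensity.

    The key for map c is ``sum(p_c * gray) / sum(p_c)`` (0 for an all-zero
    map); ties keep the original relative order.  Three-map stacks are
    renamed Nuclei/Stroma/Lumen (darkest to lightest).
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.shape != stack.shape:
        raise InvalidInputError("gray image must align with the maps")
    keys = []
    for pmap in stack.maps:
        mass = float(pmap.sum())
        keys.append(float((pmap * g).sum() / mass) if mass > 0 else 0.0)
    order = np.argsort(np.asarray(keys), kind="stable")
    names = tuple(stack.class_names[i] for i in order)
    if stack.n_maps == len(CLUSTER_NAMES_BY_INTENSITY):
        names = CLUSTER_NAMES_BY_INTENSITY
    return PosteriorMapStack(
        maps=stack.maps[order],
        class_names=names,
        order_key=tuple(keys[i] for i in order),
    )


def reinsert_dab(stack: PosteriorMapStack, mask: np.ndarray) -> PosteriorMapStack:
    """Append the crisp DAB map as the last class.

    Masked pixels must carry zero posterior in every cluster map (they were
    removed before clustering); the result sums to 1 at every pixel.
    """
    m = np.asarray(mask, dtype=bool)
    if m.shape != stack.shape:
        raise InvalidInputError("mask must align with the maps")
    if np.any(stack.maps[:, m] > 1e-12):
        raise ConsistencyError(
            "masked pixels carry nonzero cluster posterior; the mask does not "
            "match the clustering"
        )
    dab = m.astype(np.float64)[None]
    return PosteriorMapStack(
        maps=np.concatenate([stack.maps, dab], axis=0),
        class_names=stack.class_names + ("DAB",),
        order_key=stack.order_key,
    )


@dataclass(frozen=True)
class ClassFractions:
    """Area fractions of the four classes, kept as exact pixel counts.

    Float fractions are derived on demand; the published display convention
    rounds to 2 decimals.
    """

    counts: tuple[int, int, int, int]  # lumen, stroma, nuclei, dab
    total: int

    @property
    def lumen(self) -> float:
        return self.counts[0] / self.total

    @property
    def stroma(self) -> float:
        return self.counts[1] / self.total

    @property
    def nuclei(self) -> float:
        return self.counts[2] / self.total

    @property
    def dab(self) -> float:
        return self.counts[3] / self.total

    def as_dict(self) -> dict[str, float]:
        return {
            "lumen": self.lumen,
            "stroma": self.stroma,
            "nuclei": self.nuclei,
            "dab": self.dab,
        }

    def rounded(self) -> dict[str, float]:
        return {k: round(v, 2) for k, v in self.as_dict().items()}

    def exact_sum(self) -> Fraction:
        """Exact (rational) sum of the fractions; 1 by construction."""
        return sum(
            (Fraction(c, self.total) for c in self.counts), start=Fraction(0)
        )


def map_labels(stack: PosteriorMapStack) -> np.ndarray:
    """Per-pixel MAP class indices; ties break toward the later map."""
    if stack.n_maps == 0:
        raise InvalidInputError("empty stack")
    rev = np.argmax(stack.maps[::-1], axis=0)
    return (stack.n_maps - 1) - rev


def quantify_fractions(stack: PosteriorMapStack) -> ClassFractions:
    """MAP-rule area fractions of the four classes Lumen/Stroma/Nuclei/DAB."""
    required = {"Lumen", "Stroma", "Nuclei", "DAB"}
    if stack.n_maps != 4 or set(stack.class_names) != required:
        raise InvalidInputError(
            f"expected the 4 maps {sorted(required)}, got {stack.class_names}"
        )
    labels = map_labels(stack)
    total = labels.size
    counts = {
        name: int(np.sum(labels == i)) for i, name in enumerate(stack.class_names)
    }
    return ClassFractions(
        counts=(counts["Lumen"], counts["Stroma"], counts["Nuclei"], counts["DAB"]),
        total=total,
    )


def pseudocolor(stack: PosteriorMapStack, palette: np.ndarray) -> np.ndarray:
    """Blend one color per class by the posteriors (convex combination)."""
    pal = np.asarray(palette, dtype=np.float64)
    if pal.shape != (stack.n_maps, 3):
        raise InvalidInputError(
            f"palette must provide one RGB color per map ({stack.n_maps} x 3)"
        )
    return np.einsum("chw,cd->hwd", stack.maps, pal)


def save_stack(stack: PosteriorMapStack, outdir: str | Path, image_id: str) -> Path:
    """Write per-class 16-bit PNGs plus a JSON manifest; returns its path."""
    from .io import save_posterior_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, pmap in zip(stack.class_names, stack.maps):
        fname = f"{image_id}_{name.lower()}.png"
        save_posterior_map(outdir / fname, pmap)
        files.append(fname)
    manifest = {
        "format": "stainseg-posterior-stack",
        "image_id": image_id,
        "class_names": list(stack.class_names),
        "order_key": list(stack.order_key),
        "files": files,
    }
    path = outdir / f"{image_id}_stack.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_stack(manifest_path: str | Path) -> tuple[str, PosteriorMapStack]:
    """Load a stack written by :func:`save_stack`; returns (image_id, stack)."""
    from .io import load_posterior_map

    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    if doc.get("format") != "stainseg-posterior-stack":
        raise InvalidInputError(f"{manifest_path}: not a stack manifest")
    maps = np.stack(
        [load_posterior_map(manifest_path.parent / f) for f in doc["files"]]
    )
    stack = PosteriorMapStack(
        maps=maps,
        class_names=tuple(doc["class_names"]),
        order_key=tuple(doc.get("order_key", ())),
    )
    return doc["image_id"], stack
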