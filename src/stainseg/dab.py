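"""Supervised detection of the DAB chromogen.

DAB is light-scattering, so optical-density unmixing is unreliable; instead
a quadratic (normal-Bayes) pixel classifier is trained once on labeled
regions of three classes — blue hematoxylin, brown DAB, and white lumen —
and applied to every image before clustering.  The classifier does not act
on raw RGB but in a dissimilarity space: a representation set of prototype
pixels is drawn at random per class, and each pixel is described by its
Euclidean distances to all prototypes.  Per-class Gaussians (ridge-
regularized covariances) with count-proportional priors give posteriors;
pixels whose MAP class is DAB are masked out prior to fuzzy clustering.

Distances are computed in the preprocessed RGB feature space (after
downscaling and smoothing, before stain-space normalization/PCA); the
preprocessing fingerprint is stored with the serialized model so a
classifier is never applied under a different pipeline configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    NotFittedError,
    NumericError,
)
from .labels import STAIN_CLASS_ORDER, StainClass
from .preprocess import image_to_features, validate_rgb

SERIAL_VERSION = 1

#: Ridge added to each class covariance: RIDGE_REL * trace(cov) / P.
RIDGE_REL = 1e-6


@dataclass(frozen=True)
class LabeledPixelSet:
    """Labeled training pixels: N x 3 preprocessed RGB rows + stain labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        l = np.asarray(self.labels)
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] != l.shape[0]:
            raise InvalidInputError("features must be N x 3 with N labels")
        valid = {int(c) for c in STAIN_CLASS_ORDER}
        if not set(np.unique(l)).issubset(valid):
            raise InvalidInputError(f"labels must be drawn from {sorted(valid)}")

    @property
    def class_counts(self) -> dict[StainClass, int]:
        l = np.asarray(self.labels)
        return {c: int(np.sum(l == c)) for c in STAIN_CLASS_ORDER}

    def subset(self, idx: np.ndarray) -> "LabeledPixelSet":
        return LabeledPixelSet(
            np.asarray(self.features)[idx], np.asarray(self.labels)[idx]
        )


@dataclass(frozen=True)
class PrototypeSet:
    """Representation set for the dissimilarity space."""

    prototypes: np.ndarray  # P x 3
    source_labels: np.ndarray  # P
    seed: int
    indices: np.ndarray | None = None  # positions in the originating pixel set


def assemble_training_set(
    images: list[np.ndarray], masks: list[np.ndarray]
) -> LabeledPixelSet:
    """Collect labeled pixels from (image, mask) pairs.

    Masks use the palette 0 = unlabeled, 1 = hematoxylin, 2 = DAB,
    3 = lumen; unlabeled pixels are excluded.  Every class must appear at
    least once across the inputs.
    """
    if len(images) != len(masks) or not images:
        raise InvalidInputError("need equally many images and masks (>= 1)")
    feats, labs = [], []
    for img, mask in zip(images, masks):
        arr = validate_rgb(img)
        m = np.asarray(mask)
        if m.shape != arr.shape[:2]:
            raise InvalidInputError(
                f"mask shape {m.shape} does not match image {arr.shape[:2]}"
            )
        sel = m != int(StainClass.UNLABELED)
        feats.append(arr[sel])
        labs.append(m[sel].astype(np.int64))
    features = np.concatenate(feats, axis=0)
    labels = np.concatenate(labs, axis=0)
    for c in STAIN_CLASS_ORDER:
        if not np.any(labels == int(c)):
            raise InsufficientDataError(f"class {c.name} has no labeled pixels")
    return LabeledPixelSet(features, labels)


def select_prototypes(
    train: LabeledPixelSet, n_per_class: int, seed: int
) -> PrototypeSet:
    """Draw ``n_per_class`` prototypes per class without replacement."""
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    counts = train.class_counts
    smallest = min(counts.values())
    if n_per_class > smallest:
        raise InsufficientDataError(
            f"n_per_class={n_per_class} exceeds smallest class count {smallest}"
        )
    rng = np.random.default_rng(seed)
    labels = np.asarray(train.labels)
    chosen: list[np.ndarray] = []
    for c in STAIN_CLASS_ORDER:
        members = np.flatnonzero(labels == int(c))
        chosen.append(rng.choice(members, size=n_per_class, replace=False))
    idx = np.concatenate(chosen)
    return PrototypeSet(
        prototypes=np.asarray(train.features)[idx].copy(),
        source_labels=labels[idx].copy(),
        seed=seed,
        indices=idx,
    )


def to_dissimilarity(features: np.ndarray, prototypes: PrototypeSet) -> np.ndarray:
    """Euclidean distances from each object to each prototype (N x P)."""
    rows = np.asarray(features, dtype=np.float64)
    protos = np.asarray(prototypes.prototypes, dtype=np.float64)
    if rows.ndim != 2 or rows.shape[1] != protos.shape[1]:
        raise InvalidInputError(
            f"feature dimension {rows.shape} does not match prototypes "
            f"{protos.shape}"
        )
    return cdist(rows, protos, metric="euclidean")


@dataclass
class DabClassifier:
    """Quadratic (normal-Bayes) discriminant in dissimilarity space."""

    prototype_set: PrototypeSet | None = None
    class_order: tuple[int, ...] = tuple(int(c) for c in STAIN_CLASS_ORDER)
    means: np.ndarray | None = None  # C x P
    covariances: np.ndarray | None = None  # C x P x P
    priors: np.ndarray | None = None  # C
    config_fingerprint: str | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)
    _logdet: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self.means is not None

    def _prepare(self) -> None:
        """Cache Cholesky factors and log-determinants of the covariances."""
        chols, logdets = [], []
        for cov in self.covariances:
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise NumericError(
                    "class covariance is singular even after ridge "
                    "regularization; raise the ridge or lower the prototype "
                    "count"
                ) from exc
            chols.append(chol)
            logdets.append(2.0 * np.sum(np.log(np.diag(chol))))
        self._chol = np.stack(chols)
        self._logdet = np.asarray(logdets)

    def log_joint(self, dissim: np.ndarray) -> np.ndarray:
        """log prior + log Gaussian density per class (N x C)."""
        if not self.is_fitted:
            raise NotFittedError("classifier has not been fitted")
        if self._chol is None:
            self._prepare()
        d = np.asarray(dissim, dtype=np.float64)
        p = self.means.shape[1]
        if d.ndim != 2 or d.shape[1] != p:
            raise InvalidInputError(f"dissimilarity rows must have dimension {p}")
        out = np.empty((d.shape[0], len(self.class_order)))
        for c in range(len(self.class_order)):
            centered = d - self.means[c]
            # Mahalanobis distance via a triangular solve on the Cholesky factor
            y = solve_triangular(self._chol[c], centered.T, lower=True)
            maha = np.sum(y * y, axis=0)
            out[:, c] = (
                np.log(self.priors[c])
                - 0.5 * (p * np.log(2.0 * np.pi) + self._logdet[c] + maha)
            )
        return out

    def posteriors(self, dissim: np.ndarray) -> np.ndarray:
        """Class posteriors (rows sum to 1), columns in ``class_order``."""
        lj = self.log_joint(dissim)
        lj -= lj.max(axis=1, keepdims=True)
        w = np.exp(lj)
        return w / w.sum(axis=1, keepdims=True)


def fit_quadratic(
    dissim: np.ndarray,
    labels: np.ndarray,
    regularization: float | None = None,
) -> DabClassifier:
    """Fit per-class Gaussians with ridge-regularized covariances.

    ``regularization`` is the ridge added to each covariance diagonal; by
    default it is ``1e-6 * trace(cov) / P`` per class, which floors the
    near-zero eigenvalues that arise because distance vectors to P
    prototypes of 3-D pixels lie close to a 3-manifold.
    """
    d = np.asarray(dissim, dtype=np.float64)
    l = np.asarray(labels)
    if d.ndim != 2 or d.shape[0] != l.shape[0]:
        raise InvalidInputError("dissimilarity rows must match labels")
    p = d.shape[1]
    present = set(np.unique(l).tolist())
    classes = tuple(int(c) for c in STAIN_CLASS_ORDER if int(c) in present)
    if len(classes) < 2:
        raise InsufficientDataError("need at least 2 classes to fit a classifier")
    means, covs, counts = [], [], []
    for c in classes:
        rows = d[l == c]
        if rows.shape[0] < 2:
            raise InsufficientDataError(f"class {c} needs >= 2 samples")
        mu = rows.mean(axis=0)
        cov = np.cov(rows, rowvar=False).reshape(p, p)
        lam = regularization
        if lam is None:
            lam = RIDGE_REL * np.trace(cov) / p
            if lam <= 0:  # all-identical class: fall back to an absolute floor
                lam = 1e-12
        cov = cov + lam * np.eye(p)
        means.append(mu)
        covs.append(cov)
        counts.append(rows.shape[0])
    counts = np.asarray(counts, dtype=np.float64)
    clf = DabClassifier(
        class_order=classes,
        means=np.stack(means),
        covariances=np.stack(covs),
        priors=counts / counts.sum(),
    )
    clf._prepare()
    return clf


def train_classifier(
    train: LabeledPixelSet,
    n_per_class: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    regularization: float | None = None,
) -> DabClassifier:
    """Select prototypes, build the dissimilarity space, fit the quadratic."""
    protos = select_prototypes(train, n_per_class, seed)
    dissim = to_dissimilarity(train.features, protos)
    clf = fit_quadratic(dissim, train.labels, regularization=regularization)
    clf.prototype_set = protos
    clf.config_fingerprint = cfg.fingerprint() if cfg is not None else None
    return clf


def predict_classes(
    features: np.ndarray, clf: DabClassifier
) -> tuple[np.ndarray, np.ndarray]:
    """MAP labels and posteriors for N x 3 preprocessed RGB rows."""
    if not clf.is_fitted or clf.prototype_set is None:
        raise NotFittedError("classifier has not been fitted")
    dissim = to_dissimilarity(features, clf.prototype_set)
    post = clf.posteriors(dissim)
    labels = np.asarray(clf.class_order)[np.argmax(post, axis=1)]
    return labels, post


def dab_mask(img: np.ndarray, clf: DabClassifier) -> np.ndarray:
    """Boolean H x W mask, true where the MAP class is DAB.

    ``img`` must have been preprocessed with the same pipeline configuration
    used at training time.
    """
    rows, shape = image_to_features(img)
    labels, _ = predict_classes(rows, clf)
    return (labels == int(StainClass.DAB)).reshape(shape)


@dataclass(frozen=True)
class FoldResult:
    test_indices: np.ndarray
    prototype_indices: np.ndarray  # global indices into the full pixel set
    error: float


def _fold_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def cross_validate(
    train: LabeledPixelSet,
    cfg: PipelineConfig,
    folds: int = 10,
    *,
    return_folds: bool = False,
):
    """Stratified k-fold CV error of the dissimilarity-space classifier.

    Prototypes are re-selected inside each training fold, so no test-fold
    pixel ever enters the representation set or the class statistics.
    """
    if folds < 2:
        raise InvalidInputError("folds must be >= 2")
    counts = train.class_counts
    if min(counts.values()) < folds:
        raise InsufficientDataError(
            f"smallest class ({min(counts.values())}) is below fold count {folds}"
        )
    labels = np.asarray(train.labels)
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=cfg.random_seed % (2**31 - 1)
    )
    seeds = _fold_seeds(cfg.random_seed, folds)
    results: list[FoldResult] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(labels, labels)):
        tr = train.subset(tr_idx)
        n_proto = min(cfg.n_prototypes_per_class, min(tr.class_counts.values()))
        protos = select_prototypes(tr, n_proto, seeds[fold])
        d_tr = to_dissimilarity(tr.features, protos)
        clf = fit_quadratic(d_tr, tr.labels)
        clf.prototype_set = protos
        te = train.subset(te_idx)
        pred, _ = predict_classes(te.features, clf)
        err = float(np.mean(pred != np.asarray(te.labels)))
        results.append(
            FoldResult(
                test_indices=te_idx,
                prototype_indices=tr_idx[protos.indices],
                error=err,
            )
        )
    mean_error = float(np.mean([r.error for r in results]))
    if return_folds:
        return mean_error, results
    return mean_error


def learning_curve(
    train: LabeledPixelSet,
    sizes: list[int],
    repeats: int,
    seed: int,
    n_prototypes_per_class: int = 10,
) -> np.ndarray:
    """Mean held-out error per training-set size.

    For each size a stratified subsample is drawn (size // 3 per class),
    prototypes are selected within it, the quadratic is fitted, and the
    error is measured on all remaining pixels; repeated ``repeats`` times
    with fresh draws.  A size equal to the full set is evaluated on the
    training pixels themselves (resubstitution).
    """
    if repeats < 1:
        raise InvalidInputError("repeats must be >= 1")
    n_classes = len(STAIN_CLASS_ORDER)
    labels = np.asarray(train.labels)
    n_total = labels.shape[0]
    for s in sizes:
        if s < 2 * n_classes:
            raise InsufficientDataError(f"size {s} below {2 * n_classes}")
    rng = np.random.default_rng(seed)
    out = np.empty(len(sizes))
    for i, size in enumerate(sizes):
        per_class = max(2, size // n_classes)
        errs = []
        for _ in range(repeats):
            tr_parts = []
            for c in STAIN_CLASS_ORDER:
                members = np.flatnonzero(labels == int(c))
                take = min(per_class, members.shape[0])
                tr_parts.append(rng.choice(members, size=take, replace=False))
            tr_idx = np.concatenate(tr_parts)
            tr = train.subset(tr_idx)
            n_proto = min(n_prototypes_per_class, min(tr.class_counts.values()))
            protos = select_prototypes(
                tr, n_proto, int(rng.integers(0, 2**31 - 1))
            )
            clf = fit_quadratic(
                to_dissimilarity(tr.features, protos), tr.labels
            )
            clf.prototype_set = protos
            held = np.setdiff1d(np.arange(n_total), tr_idx)
            ev = train.subset(held) if held.size else tr
            pred, _ = predict_classes(ev.features, clf)
            errs.append(float(np.mean(pred != np.asarray(ev.labels))))
        out[i] = float(np.mean(errs))
    return out


def save_classifier(clf: DabClassifier, path: str | Path) -> None:
    """Serialize a fitted classifier as versioned JSON."""
    if not clf.is_fitted or clf.prototype_set is None:
        raise NotFittedError("cannot serialize an unfitted classifier")
    doc = {
        "format": "stainseg-dab-classifier",
        "version": SERIAL_VERSION,
        "class_order": list(clf.class_order),
        "prototypes": np.asarray(clf.prototype_set.prototypes).tolist(),
        "prototype_labels": np.asarray(clf.prototype_set.source_labels).tolist(),
        "prototype_seed": int(clf.prototype_set.seed),
        "means": np.asarray(clf.means).tolist(),
        "covariances": np.asarray(clf.covariances).tolist(),
        "priors": np.asarray(clf.priors).tolist(),
        "config_fingerprint": clf.config_fingerprint,
    }
    Path(path).write_text(json.dumps(doc))


def load_classifier(path: str | Path) -> DabClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "stainseg-dab-classifier":
        raise InvalidInputError(f"{path}: not a stainseg classifier file")
    if doc.get("version") != SERIAL_VERSION:
        raise InvalidInputError(f"{path}: unsupported version {doc.get('version')}")
    clf = DabClassifier(
        prototype_set=PrototypeSet(
            prototypes=np.asarray(doc["prototypes"], dtype=np.float64),
            source_labels=np.asarray(doc["prototype_labels"], dtype=np.int64),
            seed=int(doc["prototype_seed"]),
        ),
        class_order=tuple(doc["class_order"]),
        means=np.asarray(doc["means"], dtype=np.float64),
        covariances=np.asarray(doc["covariances"], dtype=np.float64),
        priors=np.asarray(doc["priors"], dtype=np.float64),
        config_fingerprint=doc.get("config_fingerprint"),
    )
    clf._prepare()
    return clf
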