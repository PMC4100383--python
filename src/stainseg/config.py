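"""Pipeline configuration.

All stages of the pipeline read their parameters from a single
:class:`PipelineConfig`.  The defaults reproduce the published protocol:
images are downscaled to 25% with bicubic interpolation, smoothed with a
per-channel Gaussian of sigma 2 px, non-DAB pixels are clustered with fuzzy
k-means (k = 3, fuzzifier m = 2), and paired-antibody calls use a per-map
correlation threshold of 0.5 combined by the product rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class PipelineConfig:
    #: Linear downscale factor applied before smoothing, in (0, 1].
    downscale_factor: float = 0.25
    #: Standard deviation (px) of the per-channel Gaussian low-pass filter.
    gaussian_sigma: float = 2.0
    #: Number of fuzzy k-means clusters for the non-DAB pixels.
    k_clusters: int = 3
    #: Fuzzifier exponent m of fuzzy k-means (> 1).
    fuzzifier_m: float = 2.0
    #: Per-map correlation threshold; the pairing threshold is this value
    #: raised to the number of posterior maps.
    per_map_threshold: float = 0.5
    #: Prototypes drawn per class for the dissimilarity representation.
    n_prototypes_per_class: int = 10
    #: Master seed for every stochastic stage.
    random_seed: int = 0
    #: Per-axis scale weights applied after the PCA rotation.
    scale_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: Fuzzy k-means convergence tolerance on the max membership change.
    fcm_tol: float = 1e-5
    #: Fuzzy k-means iteration cap.
    fcm_max_iter: int = 300
    #: Minimum overlap (fraction of the smaller map area) for a correlation
    #: offset to be considered valid.
    min_overlap_frac: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.downscale_factor <= 1.0:
            raise InvalidInputError("downscale_factor must be in (0, 1]")
        if self.gaussian_sigma < 0:
            raise InvalidInputError("gaussian_sigma must be >= 0")
        if self.k_clusters < 1:
            raise InvalidInputError("k_clusters must be >= 1")
        if self.fuzzifier_m <= 1:
            raise InvalidInputError("fuzzifier_m must be > 1")
        if not 0.0 < self.per_map_threshold < 1.0:
            raise InvalidInputError("per_map_threshold must be in (0, 1)")
        if self.n_prototypes_per_class < 1:
            raise InvalidInputError("n_prototypes_per_class must be >= 1")
        if len(self.scale_weights) != 3 or any(w <= 0 for w in self.scale_weights):
            raise InvalidInputError("scale_weights must be 3 positive reals")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale_weights"] = list(self.scale_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scale_weights" in d:
            d["scale_weights"] = tuple(d["scale_weights"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced (CLI flag overrides)."""
        return replace(self, **kwargs)

    def fingerprint(self) -> str:
        """Stable short hash of the configuration, stored in serialized models
        so a classifier is never applied under a different preprocessing."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
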