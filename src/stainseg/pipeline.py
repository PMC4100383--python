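"""End-to-end orchestration: segment batches and match batches.

The full chain per image is: preprocess -> DAB mask (trained classifier)
-> stain-space transform of the non-DAB pixels -> fuzzy k-means ->
posterior maps ordered by mean intensity -> DAB reinserted as the fourth
map -> MAP-rule class fractions.  Batches isolate failures per image so a
single unreadable file never aborts a tissue-microarray run.  All
randomness flows from one top-level seed expanded into per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dab import DabClassifier, dab_mask
from .exceptions import InvalidInputError
from .io import load_rgb_image
from .match import similarity_matrix
from .preprocess import (
    fit_stain_space,
    image_to_features,
    preprocess_image,
    stain_space_transform,
)
from .segment import (
    ClassFractions,
    PosteriorMapStack,
    fuzzy_kmeans,
    load_stack,
    memberships_to_maps,
    order_maps,
    quantify_fractions,
    reinsert_dab,
    save_stack,
)

logger = logging.getLogger("stainseg")


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master."""
    stage_key = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([master % (2**31 - 1), stage_key, index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def train_default_classifier(
    cfg: PipelineConfig,
    seed: int,
    n_phantoms: int = 3,
    pixels_per_class: int = 1000,
) -> "DabClassifier":
    """Train a DAB classifier on phantom-derived labeled regions.

    Convenience for synthetic workflows: generates DAB-rich training
    phantoms, samples region-interior pixels per stain class, preprocesses
    with ``cfg`` and fits the dissimilarity-space quadratic.
    """
    from .dab import assemble_training_set, train_classifier
    from .phantom import (
        default_training_spec,
        generate_phantom,
        generate_training_regions,
    )

    outs = [
        generate_phantom(default_training_spec(derive_seed(seed, "phantom", i)))
        for i in range(n_phantoms)
    ]
    images, masks = generate_training_regions(
        outs, pixels_per_class, seed=derive_seed(seed, "regions")
    )
    pre = [preprocess_image(im, cfg) for im in images]
    train = assemble_training_set(pre, masks)
    return train_classifier(
        train, cfg.n_prototypes_per_class, derive_seed(seed, "prototypes"), cfg=cfg
    )


@dataclass(frozen=True)
class SegmentationResult:
    stack: PosteriorMapStack  # 4 maps: Nuclei, Stroma, Lumen, DAB (ordered)
    fractions: ClassFractions
    mask: np.ndarray  # DAB mask on the preprocessed grid
    preprocessed: np.ndarray


def segment_image(
    img: np.ndarray,
    clf: DabClassifier,
    cfg: PipelineConfig,
    seed: int | None = None,
) -> SegmentationResult:
    """Segment one raw RGB image into the 4-class posterior stack."""
    pre = preprocess_image(img, cfg)
    mask = dab_mask(pre, clf)
    rows, shape = image_to_features(pre)
    flat_mask = mask.ravel()
    non_dab = np.flatnonzero(~flat_mask)
    k = cfg.k_clusters
    if non_dab.size < k:
        raise InvalidInputError(
            f"only {non_dab.size} non-DAB pixels; cannot cluster k={k}"
        )
    space = fit_stain_space(rows[non_dab], cfg.scale_weights)
    feats = stain_space_transform(rows[non_dab], space)
    fcm_seed = seed if seed is not None else derive_seed(cfg.random_seed, "fcm")
    clustering = fuzzy_kmeans(
        feats,
        k=k,
        m=cfg.fuzzifier_m,
        tol=cfg.fcm_tol,
        max_iter=cfg.fcm_max_iter,
        seed=fcm_seed,
    )
    stack = memberships_to_maps(clustering, non_dab, shape)
    gray = pre.mean(axis=2)
    stack = order_maps(stack, gray)
    stack = reinsert_dab(stack, mask)
    fractions = quantify_fractions(stack)
    return SegmentationResult(
        stack=stack, fractions=fractions, mask=mask, preprocessed=pre
    )


@dataclass
class RunReport:
    config_fingerprint: str
    seed: int
    tool_version: str
    processed: list[str] = dataclasses.field(default_factory=list)
    failed: dict[str, str] = dataclasses.field(default_factory=dict)
    fractions: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    similarity_matrix_path: str | None = None
    pair_calls_path: str | None = None
    threshold: float | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def run_segment_batch(
    manifest: list[tuple[str, str | Path | np.ndarray]],
    clf: DabClassifier,
    cfg: PipelineConfig,
    outdir: str | Path,
) -> RunReport:
    """Segment a batch of (image_id, path-or-array) entries.

    Per-image failures are logged and skipped; every input ends up either
    in ``processed`` or in ``failed``.  Outputs: per-image posterior stacks
    (16-bit PNGs + manifest) and a fractions CSV.
    """
    if clf.config_fingerprint is not None and clf.config_fingerprint != cfg.fingerprint():
        raise InvalidInputError(
            "classifier was trained under a different pipeline configuration "
            f"({clf.config_fingerprint} != {cfg.fingerprint()})"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_fingerprint=cfg.fingerprint(),
        seed=cfg.random_seed,
        tool_version=__version__,
    )
    rows = []
    for i, (image_id, src) in enumerate(manifest):
        try:
            img = src if isinstance(src, np.ndarray) else load_rgb_image(src)
            res = segment_image(
                img, clf, cfg, seed=derive_seed(cfg.random_seed, "fcm", i)
            )
            save_stack(res.stack, outdir, image_id)
            frac = res.fractions
            report.fractions[image_id] = frac.as_dict()
            report.processed.append(image_id)
            row = {"image_id": image_id, **frac.as_dict()}
            row.update({f"{k}_2dec": v for k, v in frac.rounded().items()})
            rows.append(row)
        except Exception as exc:  # isolate any per-image failure
            logger.error("segmentation failed for %s: %s", image_id, exc)
            report.failed[image_id] = str(exc)
    pd.DataFrame(rows).to_csv(outdir / "fractions.csv", index=False)
    report.save(outdir / "segment_report.json")
    return report


def run_match_batch(
    stacks_dir: str | Path,
    cfg: PipelineConfig,
    out_matrix: str | Path | None = None,
    out_calls: str | Path | None = None,
) -> tuple[RunReport, "pd.DataFrame"]:
    """Correlate every unordered pair of stacks found in ``stacks_dir``.

    Writes the symmetric similarity matrix (CSV with ids as header and
    index), per-pair calls, and a JSON run report recording the threshold
    ``per_map_threshold ** k``.
    """
    stacks_dir = Path(stacks_dir)
    manifests = sorted(stacks_dir.glob("*_stack.json"))
    if len(manifests) < 2:
        raise InvalidInputError(
            f"need at least 2 stacks in {stacks_dir}, found {len(manifests)}"
        )
    ids, stacks = [], []
    for mp in manifests:
        image_id, stack = load_stack(mp)
        ids.append(image_id)
        stacks.append(stack)
    sim = similarity_matrix(
        stacks,
        per_map_threshold=cfg.per_map_threshold,
        ids=ids,
        min_overlap_frac=cfg.min_overlap_frac,
    )
    matrix_df = pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids))
    call_rows = []
    for (i, j), res in sorted(sim.results.items()):
        row = {"id_a": ids[i], "id_b": ids[j]}
        row.update(
            {f"coef_{n}": c for n, c in zip(
                stacks[i].class_names, res.per_map_coefficients
            )}
        )
        row.update(
            product=res.product,
            offset_row=res.offset[0],
            offset_col=res.offset[1],
            is_paired=res.is_paired,
        )
        call_rows.append(row)
    calls_df = pd.DataFrame(call_rows)
    report = RunReport(
        config_fingerprint=cfg.fingerprint(),
        seed=cfg.random_seed,
        tool_version=__version__,
        processed=ids,
        threshold=sim.threshold,
    )
    if out_matrix is not None:
        matrix_df.to_csv(out_matrix)
        report.similarity_matrix_path = str(out_matrix)
    if out_calls is not None:
        calls_df.to_csv(out_calls, index=False)
        report.pair_calls_path = str(out_calls)
        report.save(Path(out_calls).with_suffix(".report.json"))
    return report, matrix_df
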