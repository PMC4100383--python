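"""Synthetic stained-tissue phantoms with ground truth.

The generator emulates the color geometry of DAB/hematoxylin brightfield
images: pixel colors live on two branches in RGB space — a brown DAB
branch and a blue hematoxylin branch that fades toward white — with the
hematoxylin branch carrying a dark cluster (nuclei) and a light cluster
(stroma), and near-white lumen at its end.  Geometry is produced by
thresholding Gaussian-smoothed white noise at quantiles chosen to hit the
requested class area fractions, which yields seeded, tissue-like connected
blobs.  Three spatial scales are used, as in real sections: broad lumen /
tissue compartments, mid-sized DAB-positive patches, and fine nuclear
speckle scattered through the tissue.  Adjacent-section pairs are modelled
as a translation of the same geometry with optional partial structure
replacement and fresh color noise, mimicking how consecutive microtome
sections share structures but never match exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .exceptions import InsufficientDataError, InvalidInputError
from .labels import StainClass, TissueClass

#: Default class colors (RGB in [0,1]), on the two stain branches:
#: near-white lumen, light-blue stroma, dark-blue nuclei, brown DAB.
DEFAULT_STAIN_COLORS: dict[TissueClass, tuple[float, float, float]] = {
    TissueClass.LUMEN: (0.95, 0.95, 0.95),
    TissueClass.STROMA: (0.75, 0.78, 0.88),
    TissueClass.NUCLEI: (0.35, 0.35, 0.60),
    TissueClass.DAB: (0.45, 0.30, 0.15),
}

#: Background gray used to fill borders exposed by translation (slide glass
#: reads as near-white lumen).
BACKGROUND_FILL = TissueClass.LUMEN

#: Margin (px) eroded from class regions before sampling training pixels,
#: emulating a human marking region interiors rather than boundaries.
TRAINING_REGION_MARGIN = 1


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 320
    width: int = 320
    #: Target area fractions in the order (lumen, stroma, nuclei, dab).
    class_fractions: tuple[float, float, float, float] = (0.40, 0.30, 0.20, 0.10)
    stain_colors: dict[TissueClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAIN_COLORS)
    )
    #: Per-channel Gaussian color noise (std).
    color_jitter_sigma: float = 0.03
    #: Characteristic size (px) of the broad lumen/tissue compartments:
    #: sigma of the smoothed noise field.
    blob_scale: float = 20.0
    #: Characteristic size of DAB-positive patches.
    dab_blob_scale: float = 12.0
    #: Characteristic size of the nuclear speckle inside tissue.
    nuclei_blob_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise InvalidInputError("phantom dimensions must be positive")
        f = np.asarray(self.class_fractions, dtype=np.float64)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                "class_fractions must be 4 nonnegative reals summing to 1"
            )
        for c, rgb in self.stain_colors.items():
            if np.any(np.asarray(rgb) < 0) or np.any(np.asarray(rgb) > 1):
                raise InvalidInputError(f"stain color for {c} outside [0,1]")


@dataclass(frozen=True)
class PhantomOutput:
    image: np.ndarray  # H x W x 3 in [0,1]
    truth: np.ndarray  # H x W labels over TissueClass
    spec: PhantomSpec


def _smooth_field(rng: np.random.Generator, shape, blob_scale: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=blob_scale, mode="wrap")


def _geometry(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Label map hitting the requested fractions up to pixel rounding.

    Three independent smoothed fields are thresholded at (conditional)
    quantiles: a mid-scale field places DAB patches, a broad field carves
    lumen out of the remainder, and a fine field scatters nuclei through
    the remaining tissue (stroma).
    """
    shape = (spec.height, spec.width)
    f_lumen, f_stroma, f_nuclei, f_dab = spec.class_fractions
    truth = np.full(shape, int(TissueClass.LUMEN), dtype=np.uint8)

    field_dab = _smooth_field(rng, shape, spec.dab_blob_scale)
    dab = field_dab < np.quantile(field_dab, f_dab) if f_dab > 0 else np.zeros(
        shape, dtype=bool
    )
    truth[dab] = int(TissueClass.DAB)

    rest = ~dab
    denom = f_lumen + f_stroma + f_nuclei
    if rest.any() and denom > 0:
        field_coarse = _smooth_field(rng, shape, spec.blob_scale)
        q_lum = f_lumen / denom
        if q_lum > 0:
            t_lum = np.quantile(field_coarse[rest], 1.0 - q_lum)
            lumen = rest & (field_coarse > t_lum)
        else:
            lumen = np.zeros(shape, dtype=bool)
        tissue = rest & ~lumen
        if tissue.any() and f_stroma + f_nuclei > 0:
            field_fine = _smooth_field(rng, shape, spec.nuclei_blob_scale)
            q_nuc = f_nuclei / (f_stroma + f_nuclei)
            vals = field_fine[tissue]
            t_nuc = np.quantile(vals, q_nuc) if q_nuc > 0 else -np.inf
            lab = np.where(
                vals <= t_nuc, int(TissueClass.NUCLEI), int(TissueClass.STROMA)
            ).astype(np.uint8)
            truth[tissue] = lab
    return truth


def _render(
    rng: np.random.Generator, truth: np.ndarray, spec: PhantomSpec
) -> np.ndarray:
    colors = np.zeros((4, 3))
    for c, rgb in spec.stain_colors.items():
        colors[int(c)] = rgb
    img = colors[truth]
    if spec.color_jitter_sigma > 0:
        img = img + rng.normal(0.0, spec.color_jitter_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Deterministically generate one phantom image plus its label map."""
    rng = np.random.default_rng(spec.seed)
    truth = _geometry(rng, spec)
    image = _render(rng, truth, spec)
    return PhantomOutput(image=image, truth=truth, spec=spec)


def _translate_labels(
    truth: np.ndarray, offset: tuple[int, int], fill: int
) -> np.ndarray:
    h, w = truth.shape
    dr, dc = offset
    out = np.full_like(truth, fill)
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = truth[src_r, src_c]
    return out


def generate_adjacent_pair(
    spec: PhantomSpec,
    offset: tuple[int, int],
    structure_change: float,
    seed: int,
) -> tuple[PhantomOutput, PhantomOutput]:
    """Generate two phantoms related like adjacent tissue sections.

    The second image carries the first's geometry translated by ``offset``
    (exposed borders fill with lumen background), with a fraction
    ``structure_change`` of the area re-drawn from an independent geometry
    — 0 gives a pure translation, 1 a completely unrelated section — and
    fresh color noise.
    """
    dr, dc = offset
    if abs(dr) >= spec.height or abs(dc) >= spec.width:
        raise InvalidInputError("offset must be smaller than the image dimensions")
    if not 0.0 <= structure_change <= 1.0:
        raise InvalidInputError("structure_change must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth1 = _geometry(rng, spec)
    img1 = _render(rng, truth1, spec)
    first = PhantomOutput(image=img1, truth=truth1, spec=spec)
    return _continue_section(
        first, offset, structure_change, int(rng.integers(0, 2**31 - 1))
    )


def generate_paired_cohort(
    group_sizes: list[int],
    spec: PhantomSpec,
    max_offset: int,
    structure_change: float,
    seed: int,
) -> tuple[list[PhantomOutput], set[tuple[int, int]]]:
    """Generate a cohort of phantoms with planted adjacent-section groups.

    ``group_sizes`` lists the size of each group (1 = singleton); members
    of a group are chained translations of one geometry (each link drawing
    a fresh offset with components in [-max_offset, max_offset] and
    re-drawing a ``structure_change`` fraction of the area), while
    different groups are independent.  Returns the phantoms in order plus
    the set of index pairs (i < j) that belong to the same group.
    """
    rng = np.random.default_rng(seed)
    outputs: list[PhantomOutput] = []
    true_pairs: set[tuple[int, int]] = set()
    for g, size in enumerate(group_sizes):
        if size < 1:
            raise InvalidInputError("group sizes must be >= 1")
        start = len(outputs)
        member_seed = int(rng.integers(0, 2**31 - 1))
        spec_g = PhantomSpec(
            height=spec.height,
            width=spec.width,
            class_fractions=spec.class_fractions,
            stain_colors=spec.stain_colors,
            color_jitter_sigma=spec.color_jitter_sigma,
            blob_scale=spec.blob_scale,
            dab_blob_scale=spec.dab_blob_scale,
            nuclei_blob_scale=spec.nuclei_blob_scale,
            seed=member_seed,
        )
        first = generate_phantom(spec_g)
        outputs.append(first)
        prev = first
        for _ in range(size - 1):
            offset = (
                int(rng.integers(-max_offset, max_offset + 1)),
                int(rng.integers(-max_offset, max_offset + 1)),
            )
            # chain the next member off the previous one so a triple drifts
            # gradually, as consecutive physical sections do
            _, nxt = _continue_section(
                prev, offset, structure_change, int(rng.integers(0, 2**31 - 1))
            )
            outputs.append(nxt)
            prev = nxt
        for i in range(start, len(outputs)):
            for j in range(i + 1, len(outputs)):
                true_pairs.add((i, j))
    return outputs, true_pairs


def _continue_section(
    prev: PhantomOutput,
    offset: tuple[int, int],
    structure_change: float,
    seed: int,
) -> tuple[PhantomOutput, PhantomOutput]:
    """Derive the next section from an existing phantom (translate the
    label map, optionally replace part of the structure, fresh noise)."""
    spec = prev.spec
    dr, dc = offset
    if abs(dr) >= spec.height or abs(dc) >= spec.width:
        raise InvalidInputError("offset must be smaller than the image dimensions")
    rng = np.random.default_rng(seed)
    truth2 = _translate_labels(prev.truth, offset, int(BACKGROUND_FILL))
    if structure_change >= 1.0:
        truth2 = _geometry(rng, spec)
    elif structure_change > 0:
        alt = _geometry(rng, spec)
        change_field = _smooth_field(rng, prev.truth.shape, spec.blob_scale)
        change = change_field < np.quantile(change_field, structure_change)
        truth2 = np.where(change, alt, truth2)
    img2 = _render(rng, truth2, spec)
    return prev, PhantomOutput(image=img2, truth=truth2, spec=spec)


#: Fractions used for the phantoms a training set is assembled from: richer
#: in DAB than a typical evaluation image so every class yields ample
#: interior pixels, as one would choose fields when marking a training set.
TRAINING_FRACTIONS = (0.30, 0.28, 0.22, 0.20)


def default_training_spec(seed: int, base: PhantomSpec | None = None) -> PhantomSpec:
    """Spec for training-set phantoms (DAB-richer field mix)."""
    b = base if base is not None else PhantomSpec()
    return PhantomSpec(
        height=b.height,
        width=b.width,
        class_fractions=TRAINING_FRACTIONS,
        stain_colors=b.stain_colors,
        color_jitter_sigma=b.color_jitter_sigma,
        blob_scale=b.blob_scale,
        dab_blob_scale=b.dab_blob_scale,
        nuclei_blob_scale=b.nuclei_blob_scale,
        seed=seed,
    )


#: Grouping of the 4 tissue classes into the 3 stain classes used for
#: training the DAB detector (hematoxylin covers stroma and nuclei).
_STAIN_GROUPS: dict[StainClass, tuple[TissueClass, ...]] = {
    StainClass.HEMATOXYLIN: (TissueClass.STROMA, TissueClass.NUCLEI),
    StainClass.DAB: (TissueClass.DAB,),
    StainClass.LUMEN: (TissueClass.LUMEN,),
}


def generate_training_regions(
    outputs: list[PhantomOutput],
    pixels_per_class: int,
    seed: int,
    margin: int = TRAINING_REGION_MARGIN,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Build (images, masks) for the DAB training set from phantoms.

    Emulates manual region-of-interest selection: pixels are sampled from
    region interiors (classes eroded by ``margin``) so boundary mixtures —
    which a human would avoid — are excluded.  Masks use the palette
    0 = unlabeled, 1 = hematoxylin, 2 = DAB, 3 = lumen.
    """
    if not outputs:
        raise InvalidInputError("need at least one phantom")
    rng = np.random.default_rng(seed)
    masks = [
        np.zeros(out.truth.shape, dtype=np.uint8) for out in outputs
    ]
    struct = np.ones((3, 3), dtype=bool)
    for stain, tissues in _STAIN_GROUPS.items():
        pool: list[tuple[int, int]] = []
        for oi, out in enumerate(outputs):
            region = np.isin(out.truth, [int(t) for t in tissues])
            if margin > 0:
                region = binary_erosion(region, structure=struct, iterations=margin)
            for flat in np.flatnonzero(region):
                pool.append((oi, int(flat)))
        if len(pool) < pixels_per_class:
            raise InsufficientDataError(
                f"only {len(pool)} interior pixels available for "
                f"{stain.name}, need {pixels_per_class}"
            )
        take = rng.choice(len(pool), size=pixels_per_class, replace=False)
        for t in take:
            oi, flat = pool[t]
            masks[oi].flat[flat] = int(stain)
    return [out.image for out in outputs], masks


def save_phantom(out: PhantomOutput, outdir: str | Path, name: str) -> None:
    """Write image PNG, truth PNG (TissueClass palette) and the spec JSON."""
    from .io import save_label_mask, save_rgb_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_rgb_image(outdir / f"{name}.png", out.image)
    save_label_mask(outdir / f"{name}_truth.png", out.truth)
    spec = out.spec
    doc = {
        "height": spec.height,
        "width": spec.width,
        "class_fractions": list(spec.class_fractions),
        "stain_colors": {c.name: list(v) for c, v in spec.stain_colors.items()},
        "color_jitter_sigma": spec.color_jitter_sigma,
        "blob_scale": spec.blob_scale,
        "dab_blob_scale": spec.dab_blob_scale,
        "nuclei_blob_scale": spec.nuclei_blob_scale,
        "seed": spec.seed,
    }
    (outdir / f"{name}_spec.json").write_text(json.dumps(doc, indent=2))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    doc = json.loads(Path(path).read_text())
    colors = {
        TissueClass[k]: tuple(v) for k, v in doc.get("stain_colors", {}).items()
    } or dict(DEFAULT_STAIN_COLORS)
    return PhantomSpec(
        height=int(doc["height"]),
        width=int(doc["width"]),
        class_fractions=tuple(doc["class_fractions"]),
        stain_colors=colors,
        color_jitter_sigma=float(doc.get("color_jitter_sigma", 0.03)),
        blob_scale=float(doc.get("blob_scale", 20.0)),
        dab_blob_scale=float(doc.get("dab_blob_scale", 12.0)),
        nuclei_blob_scale=float(doc.get("nuclei_blob_scale", 5.0)),
        seed=int(doc.get("seed", 0)),
    )
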