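"""Posterior-map correlation and paired-antibody similarity.

Two segmented sections are compared map by map with normalized
cross-correlation over every integer translation.  Each map pair
contributes the absolute value of its peak coefficient; the per-map
coefficients are combined with the product rule, so a single poorly
matching map suppresses the overall similarity.  A pair is called
"paired" when the product exceeds ``t^k`` (t = 0.5 per map, hence
T = 0.125 for k = 3 maps and 0.0625 for k = 4).  The registration offset
is read from the elementwise product of the per-map correlation surfaces:
adjacent sections share one physical displacement, so a single
translation is estimated for the whole stack.  Rotation is not modelled —
orientation differences between adjacent sections are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import InvalidInputError
from .segment import PosteriorMapStack

#: Offsets whose overlap is below this fraction of the smaller map area are
#: excluded (their correlation is reported as 0 and flagged).
DEFAULT_MIN_OVERLAP_FRAC = 0.25

#: An overlap whose variance sum falls below this (times overlap size) is
#: treated as constant: correlation undefined, reported as 0 and flagged.
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class CorrelationSurface:
    """NCC values over all integer offsets.

    ``values[i, j]`` is the correlation between ``a`` and ``b`` translated
    by ``(i - origin[0], j - origin[1])``; ``invalid`` marks offsets
    excluded for insufficient overlap or constant patches.
    """

    values: np.ndarray  # (Ha+Hb-1) x (Wa+Wb-1)
    origin: tuple[int, int]
    invalid: np.ndarray  # same shape, bool

    def offset_of_index(self, i: int, j: int) -> tuple[int, int]:
        return (i - self.origin[0], j - self.origin[1])


def _sliding_rect_sums(
    x: np.ndarray, r0: np.ndarray, r1: np.ndarray, c0: np.ndarray, c1: np.ndarray
) -> np.ndarray:
    """Rectangle sums of ``x`` for every (row-bound, col-bound) combination,
    via a padded summed-area table."""
    integ = np.zeros((x.shape[0] + 1, x.shape[1] + 1))
    np.cumsum(np.cumsum(x, axis=0), axis=1, out=integ[1:, 1:])
    return (
        integ[np.ix_(r1, c1)]
        - integ[np.ix_(r0, c1)]
        - integ[np.ix_(r1, c0)]
        + integ[np.ix_(r0, c0)]
    )


def ncc_surface(
    a: np.ndarray,
    b: np.ndarray,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> CorrelationSurface:
    """Zero-normalized cross-correlation of ``a`` against ``b`` at every
    integer translation of ``b``.

    At each offset the Pearson correlation is computed over the overlapping
    region only (means and standard deviations taken over the overlap).
    Offsets with overlap below ``min_overlap_frac`` of the smaller map
    area, or with a constant patch, are set to 0 and flagged invalid.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.size == 0 or b.size == 0:
        raise InvalidInputError("maps must be nonempty 2-D arrays")
    ha, wa = a.shape
    hb, wb = b.shape
    # offset d ranges over [-(ha-1), hb-1] x [-(wa-1), wb-1]; index = d + (ha-1)
    dr = np.arange(-(ha - 1), hb)
    dc = np.arange(-(wa - 1), wb)
    origin = (ha - 1, wa - 1)

    # sum_x a(x) b(x + d) == conv(b, flip(a)) evaluated at index d + (ha-1)
    s_ab = fftconvolve(b, a[::-1, ::-1], mode="full")

    # overlap rectangles: in a -> rows [max(0,-d), min(ha, hb-d));
    #                     in b -> rows [max(0, d), min(hb, ha+d))
    ar0, ar1 = np.maximum(0, -dr), np.minimum(ha, hb - dr)
    ac0, ac1 = np.maximum(0, -dc), np.minimum(wa, wb - dc)
    br0, br1 = np.maximum(0, dr), np.minimum(hb, ha + dr)
    bc0, bc1 = np.maximum(0, dc), np.minimum(wb, wa + dc)

    n = np.outer(ar1 - ar0, ac1 - ac0).astype(np.float64)
    s_a = _sliding_rect_sums(a, ar0, ar1, ac0, ac1)
    s_aa = _sliding_rect_sums(a * a, ar0, ar1, ac0, ac1)
    s_b = _sliding_rect_sums(b, br0, br1, bc0, bc1)
    s_bb = _sliding_rect_sums(b * b, br0, br1, bc0, bc1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / n
        var_a = s_aa - s_a * s_a / n
        var_b = s_bb - s_b * s_b / n
        denom = np.sqrt(np.maximum(var_a, 0.0) * np.maximum(var_b, 0.0))
        values = cov / denom

    min_area = min_overlap_frac * min(ha * wa, hb * wb)
    invalid = (
        (n < min_area)
        | (var_a <= _VAR_EPS * n)
        | (var_b <= _VAR_EPS * n)
        | ~np.isfinite(values)
    )
    values = np.where(invalid, 0.0, values)
    values = np.clip(values, -1.0, 1.0)
    return CorrelationSurface(values=values, origin=origin, invalid=invalid)


def _argmax_with_ties(
    score: np.ndarray, origin: tuple[int, int]
) -> tuple[float, tuple[int, int]]:
    """Max of ``score`` and its offset; ties prefer the smallest offset
    magnitude, then row-major order."""
    best = float(score.max())
    cand = np.argwhere(score == best)
    offs = cand - np.asarray(origin)
    mag = np.sum(offs * offs, axis=1)
    order = np.lexsort((cand[:, 1], cand[:, 0], mag))
    i, j = cand[order[0]]
    return best, (int(i - origin[0]), int(j - origin[1]))


def best_match(surface: CorrelationSurface) -> tuple[float, tuple[int, int]]:
    """Peak absolute correlation and the offset where it occurs."""
    score = np.where(surface.invalid, -np.inf, np.abs(surface.values))
    if not np.any(np.isfinite(score)):
        return 0.0, (0, 0)
    coef, offset = _argmax_with_ties(score, surface.origin)
    return float(min(max(coef, 0.0), 1.0)), offset


@dataclass(frozen=True)
class SimilarityResult:
    per_map_coefficients: tuple[float, ...]
    product: float
    offset: tuple[int, int]
    threshold: float
    is_paired: bool


def pair_similarity(
    stack_a: PosteriorMapStack,
    stack_b: PosteriorMapStack,
    per_map_threshold: float = 0.5,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> SimilarityResult:
    """Product-rule similarity between two posterior-map stacks.

    Each map contributes the absolute peak of its own correlation surface;
    the pairing threshold is ``per_map_threshold ** k``.  The registration
    offset is the argmax of the elementwise product of the per-map absolute
    surfaces (one shared translation for the physical section pair).
    """
    if stack_a.n_maps != stack_b.n_maps:
        raise InvalidInputError(
            f"map counts differ: {stack_a.n_maps} vs {stack_b.n_maps}"
        )
    if stack_a.class_names != stack_b.class_names:
        raise InvalidInputError(
            "stacks must carry the same class names in the same order"
        )
    coefs = []
    prod_surface = None
    any_invalid = None
    origin = None
    for ma, mb in zip(stack_a.maps, stack_b.maps):
        surf = ncc_surface(ma, mb, min_overlap_frac=min_overlap_frac)
        coef, _ = best_match(surf)
        coefs.append(coef)
        absvals = np.abs(surf.values)
        if prod_surface is None:
            prod_surface = absvals.copy()
            any_invalid = surf.invalid.copy()
            origin = surf.origin
        else:
            prod_surface *= absvals
            any_invalid |= surf.invalid
    prod_surface[any_invalid] = -np.inf
    if np.any(np.isfinite(prod_surface)):
        _, offset = _argmax_with_ties(prod_surface, origin)
    else:
        offset = (0, 0)
    product = float(np.prod(coefs))
    threshold = float(per_map_threshold ** stack_a.n_maps)
    return SimilarityResult(
        per_map_coefficients=tuple(coefs),
        product=product,
        offset=offset,
        threshold=threshold,
        is_paired=product > threshold,
    )


def register_pair(
    stack_a: PosteriorMapStack, stack_b: PosteriorMapStack
) -> tuple[int, int]:
    """Translation-only registration offset of B relative to A."""
    return pair_similarity(stack_a, stack_b).offset


@dataclass(frozen=True)
class SimilarityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # n x n symmetric, unit diagonal
    results: dict[tuple[int, int], SimilarityResult]
    threshold: float


def similarity_matrix(
    stacks: list[PosteriorMapStack],
    per_map_threshold: float = 0.5,
    ids: list[str] | None = None,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> SimilarityMatrix:
    """All-pairs product-rule similarity; each unordered pair computed once."""
    if len(stacks) < 2:
        raise InvalidInputError("need at least 2 stacks")
    k = stacks[0].n_maps
    if any(s.n_maps != k for s in stacks):
        raise InvalidInputError("all stacks must have the same map count")
    if ids is None:
        ids = [f"S{i+1}" for i in range(len(stacks))]
    n = len(stacks)
    values = np.eye(n)
    results: dict[tuple[int, int], SimilarityResult] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = pair_similarity(
                stacks[i],
                stacks[j],
                per_map_threshold=per_map_threshold,
                min_overlap_frac=min_overlap_frac,
            )
            values[i, j] = values[j, i] = res.product
            results[(i, j)] = res
    return SimilarityMatrix(
        ids=tuple(ids),
        values=values,
        results=results,
        threshold=float(per_map_threshold**k),
    )
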