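# Methods

This note documents the models and procedures implemented in `stainseg`,
the parameters that matter, the design choices made where the protocol was
open, and what the synthetic phantom experiments do and do not show.

## Pipeline overview

An RGB brightfield image of a DAB/hematoxylin-stained section is processed
as: preprocess → supervised DAB detection → fuzzy clustering of the
remaining pixels → posterior-map ordering and DAB reinsertion → area
quantification; pairs of processed sections are then compared by
normalized cross-correlation of their posterior maps combined with the
product rule.

## Preprocessing (`stainseg.preprocess`)

* **Downscale**: bicubic interpolation to a linear factor (default 0.25,
  the protocol's working resolution for ~3000 px slides).  Output size is
  `round(dim × factor)`, floored at 1.  No anti-aliasing filter is added
  beyond the explicit Gaussian that follows.
* **Smoothing**: per-channel Gaussian, σ = 2 px (default), reflective
  boundaries, kernel truncated at 4σ.  Reflect avoids darkened borders on
  tissue touching the image edge; the boundary mode is an implementation
  choice, not part of the published protocol.
* **Feature space**: pixels are points in 3-D RGB.  Each channel is
  affinely normalized to [0, 1] using per-image min/max (a constant
  channel maps to 0; out-of-bound values at application time clip).  PCA
  rotates the normalized space so axis 1 carries maximal variance; all
  three components are kept.  Eigenvector signs are fixed (largest
  coefficient positive) for reproducibility.  Per-axis scale weights are
  applied after rotation; the protocol emphasizes that this rescaling
  matters for clustering but does not publish values, so they are exposed
  as configuration with default (1, 1, 1).
* Whether normalization/PCA should be fitted per image or once on a
  reference set is not specified by the protocol; fitting is per image
  (each image self-contained), and the fitted `StainSpaceModel` can be
  reused explicitly for a fit-once/apply-many workflow.

## DAB detection (`stainseg.dab`)

DAB scatters light, so optical-density stain separation is unreliable; a
supervised classifier is used instead, trained once and reused.

* **Training data**: labeled pixels of three classes — hematoxylin
  (covering both stroma and nuclei), DAB, lumen — taken from preprocessed
  images via palette masks (0 unlabeled / 1 hematoxylin / 2 DAB /
  3 lumen).
* **Dissimilarity space**: a representation set of `n_prototypes_per_class`
  (default 10) pixels per class is drawn without replacement with a seed;
  every pixel is mapped to its vector of Euclidean distances to all
  prototypes.  Distances are computed in the preprocessed RGB space (not
  the PCA-rotated space); the choice is recorded via the configuration
  fingerprint stored with the model.
* **Classifier**: per-class Gaussian (quadratic / normal-Bayes) with
  count-proportional priors.  Distance vectors of 3-D pixels lie near a
  3-manifold in prototype space, so class covariances are nearly rank-3;
  a ridge `1e-6 · trace(Σ)/P · I` floors the spectrum.  Densities are
  evaluated through Cholesky factors; posteriors by log-sum-exp.
* **Cross-validation**: stratified, seeded, default 10 folds.  Prototypes
  and class statistics are recomputed inside each training fold, so no
  held-out pixel can leak into the representation set (asserted by a
  sentinel test).
* **Learning curves**: per requested size, a stratified subsample is
  trained and scored on the held-out remainder, averaged over repeats; a
  size equal to the full set degenerates to resubstitution.

Only the DAB decision is consumed downstream: predicted hematoxylin/lumen
labels are discarded and those pixels are clustered instead.

## Clustering and quantification (`stainseg.segment`)

* **Fuzzy k-means**: standard alternating updates,
  u_ij = 1 / Σ_l (d_ij/d_il)^(2/(m−1)) and c_j = Σ u^m x / Σ u^m, with
  k = 3, m = 2 by default; convergence when the max absolute membership
  change drops below 1e-5 (cap 300 sweeps).  Centers are initialized as k
  distinct data points drawn with the seed.  A point coinciding with a
  center receives membership 1 there (split evenly over exact ties).  The
  objective Σ u^m d² is recorded each sweep and is non-increasing.
* **Posterior maps**: memberships are scattered back to the raster;
  excluded (DAB) pixels carry 0 in all cluster maps.  Maps are sorted
  ascending by the posterior-weighted mean of the grayscale image (mean of
  the three preprocessed channels); an all-zero map keys as 0 and ties
  keep input order.  Ascending order makes the darkest cluster — nuclei —
  map 0; the three cluster maps are named Nuclei, Stroma, Lumen and the
  crisp DAB map is appended last, restoring a per-pixel total of exactly 1.
  A posterior-weighted key is used rather than averaging over MAP-assigned
  pixels; the two agree on well-separated clusters.
* **Fractions**: per-pixel argmax over the four maps (ties resolve toward
  the later, lighter/DAB map — deterministic), counts divided by total
  pixels.  Counts are kept as integers so the fraction sum is exactly 1 by
  construction; display values round to 2 decimals.
* **Pseudocolor**: Σ_c posterior_c · color_c, a convex combination, for
  display only.

Clustering directly with k = 4 to absorb DAB is deliberately not offered:
the brown cluster sits too close to the hematoxylin branch for stable
unsupervised separation, which is why the supervised detector exists.

## Matching (`stainseg.match`)

* **NCC dialect**: zero-normalized cross-correlation — at each integer
  offset the Pearson correlation of the overlapping region only (means
  and variances over the overlap).  Marginal sums use exact summed-area
  tables; only the cross term uses an FFT, keeping the surface within
  1e-10 of a direct double-loop computation.
* **Validity rules**: offsets whose overlap is below 25 % of the smaller
  map area are excluded (value 0, flagged) — peaks at extreme offsets with
  a handful of pixels are meaningless.  An overlap with (near-)zero
  variance on either side has undefined correlation and is likewise 0 and
  flagged.
* **Per-map coefficient**: the maximum *absolute* surface value; ties
  prefer the smallest offset magnitude, then row-major order.
* **Product rule**: the product of the k per-map coefficients; the pairing
  threshold is `per_map_threshold^k` (0.5^3 = 0.125, 0.5^4 = 0.0625) with
  a strict `>` at the threshold.  The product is bounded by the smallest
  coefficient, so one discordant map vetoes the pair.
* **Registration**: one shared translation per section pair (sections
  share a single physical displacement), taken as the argmax of the
  elementwise product of the per-map absolute surfaces.  Per-map
  coefficients are still read at each map's own peak; on genuine pairs the
  two coincide.  Rotation is not modelled.
* **Cohorts**: all n(n−1)/2 unordered pairs are computed with no prior
  grouping assumption; the matrix is symmetric with unit diagonal.

## Phantom generator (`stainseg.phantom`)

The generator produces seeded images whose pixel colors follow the
two-branch stain geometry: near-white lumen (0.95, 0.95, 0.95), light-blue
stroma (0.75, 0.78, 0.88), dark-blue nuclei (0.35, 0.35, 0.60) on the
hematoxylin branch, and brown DAB (0.45, 0.30, 0.15) on the other branch,
plus i.i.d. Gaussian color jitter (default σ = 0.03, clipped to [0, 1]).

Geometry is built by thresholding Gaussian-smoothed white noise at
(conditional) quantiles, which hits the requested area fractions to within
pixel rounding and yields connected, tissue-like regions.  Three spatial
scales mirror real sections on a 320 × 320 raster (the working resolution
a 0.25 downscale of a typical slide produces): broad lumen/tissue
compartments (σ = 20 px), mid-sized DAB patches (σ = 12 px), and fine
nuclear speckle (σ = 5 px).  The fine scale matters beyond realism: the
nuclei map gives chance alignments of unrelated sections little to
correlate with, which is exactly the regime the product rule exploits.
These scales were fixed after pilot runs balancing two failure modes —
structures small against the σ = 2 smoothing lose boundary area to color
blending, while uniformly coarse structures let unrelated sections reach
spuriously high peak correlations.

Adjacent-section pairs translate the label map (exposed borders fill with
lumen background, like slide glass), optionally replace a
`structure_change` fraction of the area with an independent geometry
(1 = unrelated section), and redraw color noise.  Cohorts chain group
members so a triple drifts gradually, as consecutive physical sections do.

Training regions emulate a human marking class interiors: each stain-class
region is eroded by 1 px before sampling, so the most ambiguous
boundary-blend pixels are excluded while near-boundary colors remain
represented — this keeps the classifier's decision near the true boundary
mid-blend.  Training phantoms use a DAB-richer field mix
(0.30/0.28/0.22/0.20) so every class yields ample interior pixels, as one
would choose fields when assembling a training set.

**What the phantoms do not model**: light-scattering optics and stain
intensity gradients, chromatic variation between slides, touching/
overlapping nuclei, genuine anatomy (glands, vessels), rotation or
deformation between sections, and scanner noise that is not i.i.d.
Passing the synthetic suite therefore validates the decision logic and the
numerics — not clinical-grade segmentation accuracy on real slides.

## Study-scale choices and numerical notes

* Synthetic experiments run the pipeline at `downscale_factor = 1.0`
  because phantoms are generated directly at the post-downscale working
  resolution; the default 0.25 applies to full-resolution slide images.
* Problem sizes: classifier training/CV uses 3 phantoms × 1000 px per
  class; fraction recovery uses noiseless 320² phantoms; registration uses
  planted offsets up to ±15 px; pairing cohorts hold 13 images in five
  planted groups (one triple) plus two singletons.
* All randomness flows from one master seed expanded per stage via
  `SeedSequence` (CRC-keyed stage names, values < 2³¹).
* Degenerate inputs have defined behaviour throughout: constant images
  refuse PCA (fewer than two distinct colors), empty posterior maps key as
  0 when ordering, a pixel on a cluster center takes membership 1, and
  constant correlation patches report 0 and are flagged rather than NaN.

## Known limitations

* Area fractions on phantoms are accurate to ~0.03 per class; the floor is
  set by σ = 2 smoothing blending colors along region boundaries, which no
  pixel-wise classifier can undo.
* The per-image PCA/normalization makes each segmentation self-contained
  but means cluster geometry can differ between images with very different
  compositions; map ordering by intensity is what keeps classes aligned
  across sections.
* The pairing threshold 0.5^k is a protocol constant, not estimated from
  data; on real slides values close to the threshold warrant review (real
  cohorts show genuine pairs only slightly above it).
* Translation-only registration assumes negligible rotation between
  adjacent sections.
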