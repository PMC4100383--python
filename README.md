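# stainseg

Automated segmentation of DAB/hematoxylin-stained brightfield tissue images
and detection of **paired antibodies** by correlating the segmentations of
adjacent tissue-microarray sections.

## The problem

In immunohistochemistry, the brown chromogen DAB (3,3′-diaminobenzidine)
marks where a primary antibody bound its target protein, while blue
hematoxylin counterstains the remaining tissue — nuclei darkly, stroma
lightly, and gland lumina stay white.  Two *paired* antibodies raised
against different epitopes of the same protein should produce concordant
staining patterns on consecutive microtome sections; checking that
concordance is a quality control on antibody specificity.  Doing it by eye
across a tissue microarray is slow, so this package automates the chain:

1. **Preprocess** — downscale to 25 % (bicubic), smooth each RGB channel
   with a Gaussian (σ = 2 px).
2. **DAB detection** — DAB scatters light and does not obey the
   Beer–Lambert law, so instead of optical-density unmixing a quadratic
   (normal-Bayes) pixel classifier is trained *once* on labeled
   hematoxylin / DAB / lumen regions.  The classifier acts in a
   *dissimilarity space*: each pixel is represented by its Euclidean
   distances to a randomly drawn prototype set, one draw per class.
3. **Clustering** — the non-DAB pixels are normalized per channel to
   [0, 1], rotated by PCA (no reduction), optionally rescaled per axis,
   and clustered with fuzzy k-means (k = 3, fuzzifier m = 2).  The soft
   memberships form posterior probability maps, sorted ascending by
   average grayscale intensity (nuclei, stroma, lumen), and the DAB mask
   is reinserted as a crisp fourth map.
4. **Quantification** — the maximum-a-posteriori rule gives crisp labels
   and per-class area fractions (reported to 2 decimals).
5. **Matching** — for two sections, each pair of corresponding posterior
   maps is compared by normalized cross-correlation over all integer
   translations; the absolute peak coefficient of each map pair is
   combined by the **product rule**, so one discordant map suppresses the
   whole score.  A pair is called *paired* when the product exceeds
   T = 0.5^k (0.125 for k = 3 maps, 0.0625 for k = 4).  Translation-only
   registration is read from the product of the correlation surfaces.

No real slide images ship with the package; a seeded phantom generator
(`stainseg.phantom`) emulates the two-branch RGB stain geometry and
adjacent-section relationships (translation, partial structure loss,
color noise) with exact ground truth, so the whole pipeline is testable
offline.

## Worked example

```python
from stainseg.config import PipelineConfig
from stainseg.phantom import PhantomSpec, generate_adjacent_pair
from stainseg.pipeline import train_default_classifier, segment_image
from stainseg.match import pair_similarity

cfg = PipelineConfig(downscale_factor=1.0, random_seed=0)
clf = train_default_classifier(cfg, seed=0)          # trained once, reused

spec = PhantomSpec(seed=42)                          # 320x320 synthetic section
sec_a, sec_b = generate_adjacent_pair(spec, offset=(9, -4),
                                      structure_change=0.1, seed=42)
res_a = segment_image(sec_a.image, clf, cfg)
res_b = segment_image(sec_b.image, clf, cfg)
print("section A fractions:", res_a.fractions.rounded())
print("section B fractions:", res_b.fractions.rounded())

sim = pair_similarity(res_a.stack, res_b.stack, per_map_threshold=0.5)
print("per-map coefficients:", [round(c, 3) for c in sim.per_map_coefficients])
print("product:", round(sim.product, 4), "threshold:", sim.threshold)
print("registration offset:", sim.offset, "paired:", sim.is_paired)
```

prints

```
section A fractions: {'lumen': 0.38, 'stroma': 0.32, 'nuclei': 0.2, 'dab': 0.09}
section B fractions: {'lumen': 0.4, 'stroma': 0.31, 'nuclei': 0.19, 'dab': 0.1}
per-map coefficients: [0.881, 0.873, 0.903, 0.886]
product: 0.6153 threshold: 0.0625
registration offset: (9, -4) paired: True
```

The two sections share 90 % of their structure and sit 9 px down / 4 px
left of each other; the pipeline recovers the planted translation exactly,
reports near-identical tissue composition, and the product 0.62 ≫ 0.0625
calls them a concordant (paired-antibody-like) pair.  An unrelated section
pair typically scores below 0.03.

The same workflow is available from the shell:

```sh
stainseg simulate --out-dir data --n 4 --seed 0
stainseg train-dab --images ... --masks ... --out model.json
stainseg segment --image data/phantom000.png --model model.json --outdir seg
stainseg match --stacks-dir seg --out sim.csv
```

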