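# phiscore

Persistent-homology scoring of immunohistochemistry (IHC) images.

Visual scoring of nuclear stains such as Ki-67 is subjective and varies
within and between observers. `phiscore` quantifies an 8-bit grayscale
field automatically using topological data analysis: the gray values
f(x, y) define a sublevel-set filtration K_i = f⁻¹([0, i]), and the
appearance and disappearance of connected components (dimension 0) and
holes (dimension 1) along the filtration are recorded as persistence
diagrams PD₀ and PD₁. Darkly stained (positive) nuclei are born at low
gray levels, unstained (negative) nuclei at mid gray levels, and both
persist until the bright background absorbs them — so after discarding
short-lived noise classes (lifetime < δ, default δ = 40), a 2-means
clustering of PD₀ separates positive from negative homology classes and
yields the **Persistent Homology Index**

    PHI = n_positive / (n_positive + n_negative),

an automated analogue of the Ki-67 labeling index. Companion metrics
describe the geometry of the two clusters: centers C₁ = (Center_x1,
Center_y1) and C₂ = (Center_x2, Center_y2) with Center_x1 < Center_x2,
within-group sums of squares WSS1 and WSS2, between-group sum of
squares BSS, and their ratio RSS = BSS / (BSS + WSS1 + WSS2); PD₁
contributes a centroid and WSS sensitive to cellularity and nuclear
atypia. A one-variable logistic regression of binary nuclear grade on
any of these scores gives a decision threshold (fitted probability 0.5)
and the accuracy/sensitivity of threshold classification.

The package is intended for image-analysis researchers and pathology
groups exploring reproducible IHC quantification. No clinical data ship
with it; a synthetic-data module generates both exactly-solvable
three-gray-level topology fixtures and IHC-like fields with known
ground truth.

## Worked example

```python
from phiscore import SyntheticParams, make_ihc_image, score_image

params = SyntheticParams(positive_fraction=0.3, n_nuclei=40, seed=42)
image, truth = make_ihc_image(params)   # 256x256, 12 positive / 28 negative nuclei
summary = score_image(image, delta=40)
print(summary.phi, summary.n_positive, summary.n_negative, round(summary.rss, 3))
```

prints

```
0.3 12 28 0.983
```

PHI = 0.3 recovers the true positive fraction exactly: after δ-filtering,
the 12 dark nuclei are the 12 low-birth classes and the 28 mid-gray
nuclei the 28 high-birth classes, and RSS ≈ 0.98 says the two clusters
are cleanly separated. `examples/` contains short narrative scripts for
each capability (toy diagrams, field scoring, cohort thresholding), and
the `phiscore` command exposes the same pipeline from the shell
(`phiscore score`, `diagram`, `classify`, `synth`, `fixture`).

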