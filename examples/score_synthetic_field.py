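"""Score a synthetic IHC-like field and compare PHI with the ground truth.

Generates a 256x256 field of 40 non-overlapping elliptical nuclei (30%
dark "positive", 70% mid-gray "negative") with mild Gaussian noise,
then runs the full pipeline: persistence diagrams, noise filtering at
delta = 40 gray levels, 2-means clustering of PD0, and the summary
metrics.  PHI should land close to the true positive fraction; C1 and
C2 are the positive and negative cluster centers on the diagram.
"""

from phiscore import SyntheticParams, make_ihc_image, score_image

params = SyntheticParams(positive_fraction=0.3, n_nuclei=40, seed=42)
image, truth = make_ihc_image(params)
print(f"ground truth: {truth.n_positive} positive / {truth.n_negative} negative nuclei")

summary = score_image(image, delta=40)
print(f"PHI        = {summary.phi:.3f}   (true fraction {params.positive_fraction})")
print(f"classes    = {summary.n_positive} positive / {summary.n_negative} negative")
print(f"C1 (pos)   = ({summary.center_x1:.1f}, {summary.center_y1:.1f})")
print(f"C2 (neg)   = ({summary.center_x2:.1f}, {summary.center_y2:.1f})")
print(f"RSS        = {summary.rss:.3f}   (near 1: clear positive/negative split)")
print(f"PD1 center = ({summary.pd1_center_x:.1f}, {summary.pd1_center_y:.1f}), "
      f"n = {summary.n_pd1}")
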