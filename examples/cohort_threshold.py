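"""Fit a binary-grade decision threshold on PHI scores of a synthetic cohort.

Simulates a small cohort: low-grade cases ("A") drawn with low positive
fractions and high-grade cases ("B") with high fractions, scores every
field with PHI, fits the one-variable logistic regression of grade on
PHI, and reports the probability-0.5 threshold with the confusion table
of threshold classification.
"""

import numpy as np

from phiscore import (
    LabeledScores,
    SyntheticParams,
    logistic_threshold,
    make_ihc_image,
    score_image,
    threshold_accuracy,
)

rng = np.random.default_rng(7)
scores, labels = [], []
for grade, lo, hi, count in (("A", 0.15, 0.55, 10), ("B", 0.35, 0.8, 10)):
    for _ in range(count):
        fraction = float(rng.uniform(lo, hi))
        image, _ = make_ihc_image(SyntheticParams(
            positive_fraction=fraction, n_nuclei=30, canvas=(192, 192),
            seed=int(rng.integers(2**31)),
        ))
        scores.append(score_image(image, delta=40).phi)
        labels.append(grade)

data = LabeledScores(np.array(scores), np.array(labels))
fit = logistic_threshold(data)
report = threshold_accuracy(data, fit.threshold)
print(f"fitted threshold on PHI: {fit.threshold:.3f}"
      + ("  (perfectly separated: gap midpoint)" if fit.separated else ""))
print(f"confusion: {report.confusion}")
print(f"accuracy {report.accuracy:.3f}, sensitivity {report.sensitivity:.3f}, "
      f"specificity {report.specificity:.3f}")
# cases scoring above the threshold are called high grade (type B)
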