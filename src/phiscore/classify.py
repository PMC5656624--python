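"""Binary nuclear-grade classification from a scalar score.

A cohort of images is split into low-grade (type A, G1) and high-grade
(type B, G2/G3) cases.  A one-variable logistic regression of the type
on a score (the pathologist's Ki-67 labeling index, or PHI) yields a
decision threshold — the score at which the fitted probability of type
B crosses 0.5 — and thresholding the score gives the confusion counts,
accuracy, sensitivity and specificity of the binary classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "LabeledScores",
    "LogisticFit",
    "ClassificationReport",
    "logistic_threshold",
    "threshold_accuracy",
]


@dataclass(frozen=True)
class LabeledScores:
    """Scores with binary A/B labels (A = low grade, B = high grade)."""

    scores: np.ndarray
    labels: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.shape != scores.shape:
            raise ValueError("scores and labels must be 1-D and the same length")
        if len(scores) < 2:
            raise ValueError("need at least 2 observations")
        unknown = set(labels.tolist()) - {self.label_a, self.label_b}
        if unknown:
            raise ValueError(f"unknown labels {sorted(map(str, unknown))}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def is_b(self) -> np.ndarray:
        return self.labels == self.label_b


@dataclass(frozen=True)
class LogisticFit:
    """Result of the one-variable logistic fit logit P(B) = a + b*score."""

    threshold: float
    intercept: float
    slope: float
    separated: bool
    converged: bool


def logistic_threshold(data: LabeledScores) -> LogisticFit:
    """Fit logit P(B) = a + b*score and return the P = 0.5 threshold -a/b.

    Fitting is Newton/IRLS (tolerance 1e-8, at most 100 iterations).
    Perfectly separated classes make the maximum-likelihood fit diverge;
    that case is detected up front and the midpoint of the separating
    gap is returned with ``separated=True``.
    """
    is_b = data.is_b
    if is_b.all() or not is_b.any():
        raise ValueError("both classes must be present to fit a threshold")
    if np.ptp(data.scores) == 0:
        raise ValueError("scores are constant; no threshold exists")

    a_scores, b_scores = data.scores[~is_b], data.scores[is_b]
    if a_scores.max() < b_scores.min():
        mid = (a_scores.max() + b_scores.min()) / 2
        return LogisticFit(mid, np.nan, np.nan, separated=True, converged=True)
    if b_scores.max() < a_scores.min():
        mid = (b_scores.max() + a_scores.min()) / 2
        return LogisticFit(mid, np.nan, np.nan, separated=True, converged=True)

    design = sm.add_constant(data.scores)
    fit = sm.Logit(is_b.astype(float), design).fit(
        method="newton", tol=1e-8, maxiter=100, disp=0
    )
    intercept, slope = fit.params
    threshold = -intercept / slope if slope != 0 else np.nan
    return LogisticFit(
        float(threshold), float(intercept), float(slope),
        separated=False, converged=bool(fit.mle_retvals.get("converged", True)),
    )


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and summary rates of threshold classification."""

    threshold: float
    a_correct: int
    a_total: int
    b_correct: int
    b_total: int
    accuracy: float
    sensitivity: float  # recall of type B (high grade)
    specificity: float  # recall of type A

    @property
    def confusion(self) -> dict[str, int]:
        return {
            "a_as_a": self.a_correct,
            "a_as_b": self.a_total - self.a_correct,
            "b_as_b": self.b_correct,
            "b_as_a": self.b_total - self.b_correct,
        }

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["confusion"] = self.confusion
        return d


def threshold_accuracy(
    data: LabeledScores, threshold: float, *, ties: str = "A"
) -> ClassificationReport:
    """Classify score > threshold as type B and tabulate the outcome.

    A score exactly at the threshold goes to type A by default (ties
    break toward the lower grade); pass ``ties="B"`` for the other
    convention.  Rates for an absent class are reported as NaN.
    """
    if ties not in ("A", "B"):
        raise ValueError("ties must be 'A' or 'B'")
    pred_b = data.scores > threshold if ties == "A" else data.scores >= threshold
    is_b = data.is_b

    b_total = int(is_b.sum())
    a_total = int((~is_b).sum())
    b_correct = int((pred_b & is_b).sum())
    a_correct = int((~pred_b & ~is_b).sum())
    total = a_total + b_total
    return ClassificationReport(
        threshold=float(threshold),
        a_correct=a_correct, a_total=a_total,
        b_correct=b_correct, b_total=b_total,
        accuracy=(a_correct + b_correct) / total,
        sensitivity=b_correct / b_total if b_total else float("nan"),
        specificity=a_correct / a_total if a_total else float("nan"),
    )
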