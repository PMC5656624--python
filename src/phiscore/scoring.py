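"""Scalar IHC metrics from persistence diagrams.

Dimension-0 classes of a stained field split into two clouds on the
diagram: darkly stained (positive) nuclei are born at low gray levels,
unstained (negative) nuclei at mid gray levels, and both persist until
the bright background absorbs them.  A deterministic 2-means clustering
of the (birth, death) points separates the clouds; the Persistent
Homology Index is then

    PHI = n_positive / (n_positive + n_negative)

counting homology classes with multiplicity.  Companion metrics are the
cluster centers C1, C2 (C1 is always the lower-birth, positive one),
the within/between sums of squares WSS1, WSS2, BSS and their ratio
RSS = BSS / (BSS + WSS1 + WSS2), and the single-group centroid and WSS
of the dimension-1 diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .image import GrayImage
from .persistence import (
    PersistenceDiagram,
    PersistencePoint,
    compute_pd0,
    compute_pd1,
    filter_noise,
)

__all__ = [
    "ClusterResult",
    "DispersionResult",
    "Pd1Summary",
    "BinnedDiagram",
    "ScoreSummary",
    "InsufficientClassesError",
    "cluster_pd0",
    "compute_phi",
    "compute_dispersion",
    "summarize_pd1",
    "bin_diagram",
    "score_image",
]

_MAX_LLOYD_ITER = 500


class InsufficientClassesError(ValueError):
    """Raised when a diagram has too few distinct classes to split in two."""


@dataclass(frozen=True)
class ClusterResult:
    """Partition of PD0 classes into positive (C1) and negative (C2) groups."""

    positive_points: tuple[PersistencePoint, ...]
    negative_points: tuple[PersistencePoint, ...]
    C1: tuple[float, float]
    C2: tuple[float, float]

    @property
    def n_positive(self) -> int:
        return sum(p.multiplicity for p in self.positive_points)

    @property
    def n_negative(self) -> int:
        return sum(p.multiplicity for p in self.negative_points)


@dataclass(frozen=True)
class DispersionResult:
    wss1: float
    wss2: float
    bss: float
    rss: float
    # RMS radii sqrt(WSS_k / n_k), the scale on which cohort tables report WSS
    wss1_rms: float
    wss2_rms: float


@dataclass(frozen=True)
class Pd1Summary:
    """Centroid and spread of the dimension-1 diagram; empty -> n = 0, NaN fields."""

    center_x: float
    center_y: float
    wss: float
    n: int
    wss_rms: float

    @property
    def is_empty(self) -> bool:
        return self.n == 0


@dataclass(frozen=True)
class BinnedDiagram:
    """Grid-binned multiplicities over [0, 2^n - 1]^2 (rows: birth, cols: death)."""

    raw: np.ndarray
    clipped: np.ndarray
    grid: int
    cap: int


def _weighted_coords(diagram: PersistenceDiagram) -> tuple[np.ndarray, np.ndarray]:
    coords, weights = diagram.as_weighted_array()
    return coords, weights


def cluster_pd0(diagram: PersistenceDiagram) -> ClusterResult:
    """Deterministic 2-means split of PD0 into positive/negative classes.

    Each homology class enters as one observation (multiplicities are
    weights, equivalent to expanding them).  Lloyd iterations start from
    the minimum- and maximum-birth classes (ties: lower death) and run
    to an exact assignment fixpoint; distance ties assign to the first
    center.  The lower-birth converged center is labeled C1 (positive),
    so Center_x1 < Center_x2 always holds on output (tie on birth: the
    lower-death center is C1).
    """
    if diagram.dimension != 0:
        raise ValueError("clustering is defined on dimension-0 diagrams")
    coords, weights = _weighted_coords(diagram)
    k = len(coords)
    if k < 2:
        raise InsufficientClassesError(
            f"need at least 2 distinct PD0 points to cluster, got {k}"
        )

    # coords are lex-sorted by (birth, death): first row is the min-birth
    # class (lowest death on ties); the max-birth class is the first row
    # of the last birth group.
    c1 = coords[0].copy()
    max_birth = coords[-1, 0]
    c2 = coords[np.argmax(coords[:, 0] == max_birth)].copy()

    assign: np.ndarray | None = None
    for _it in range(_MAX_LLOYD_ITER):
        d1 = ((coords - c1) ** 2).sum(axis=1)
        d2 = ((coords - c2) ** 2).sum(axis=1)
        new_assign = (d2 < d1).astype(int)  # tie -> cluster 0 (C1 side)

        for empty in (0, 1):
            if not np.any(new_assign == empty):
                # guard: hand the empty cluster the point farthest from
                # the surviving center, then keep iterating
                center = c2 if empty == 0 else c1
                far = int(np.argmax(((coords - center) ** 2).sum(axis=1)))
                new_assign[far] = empty
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        sel = assign == 0
        c1 = np.average(coords[sel], axis=0, weights=weights[sel])
        c2 = np.average(coords[~sel], axis=0, weights=weights[~sel])

    if assign is None or not (np.any(assign == 0) and np.any(assign == 1)):
        raise InsufficientClassesError("2-means converged with an empty cluster")

    # positive = lower-birth center; tie -> lower death
    if (c2[0], c2[1]) < (c1[0], c1[1]):
        c1, c2 = c2, c1
        assign = 1 - assign

    coord_cluster = {tuple(c.astype(int)): a for c, a in zip(coords, assign)}
    pos = tuple(p for p in diagram.points if coord_cluster[(p.birth, p.death)] == 0)
    neg = tuple(p for p in diagram.points if coord_cluster[(p.birth, p.death)] == 1)
    return ClusterResult(pos, neg, (float(c1[0]), float(c1[1])), (float(c2[0]), float(c2[1])))


def _points_array(points: tuple[PersistencePoint, ...]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([[p.birth, p.death] for p in points], dtype=float)
    weights = np.array([p.multiplicity for p in points], dtype=float)
    return coords, weights


def compute_phi(clusters: ClusterResult) -> float:
    """PHI: positive homology classes over all classes, with multiplicity."""
    n_pos, n_neg = clusters.n_positive, clusters.n_negative
    if n_pos + n_neg == 0:
        raise ValueError("cannot compute PHI of an empty clustering")
    return n_pos / (n_pos + n_neg)


def compute_dispersion(clusters: ClusterResult) -> DispersionResult:
    """Within/between sums of squares of the two clusters and RSS.

    WSS_k sums squared distances of cluster-k classes to C_k; BSS sums,
    over clusters, size times squared distance from the overall centroid
    to the cluster center; RSS = BSS / (BSS + WSS1 + WSS2), with the
    all-points-identical 0/0 case defined as 0.  Larger RSS means a
    clearer positive/negative division.
    """
    wss = []
    rms = []
    sizes = []
    centers = (np.asarray(clusters.C1), np.asarray(clusters.C2))
    all_coords = []
    all_weights = []
    for pts, center in zip((clusters.positive_points, clusters.negative_points), centers):
        coords, weights = _points_array(pts)
        w = float(((coords - center) ** 2).sum(axis=1) @ weights)
        n = float(weights.sum())
        wss.append(w)
        rms.append(math.sqrt(w / n))
        sizes.append(n)
        all_coords.append(coords)
        all_weights.append(weights)

    coords = np.vstack(all_coords)
    weights = np.concatenate(all_weights)
    overall = np.average(coords, axis=0, weights=weights)
    bss = float(sum(n * ((c - overall) ** 2).sum() for n, c in zip(sizes, centers)))
    denom = bss + wss[0] + wss[1]
    rss = bss / denom if denom > 0 else 0.0
    return DispersionResult(wss[0], wss[1], bss, rss, rms[0], rms[1])


def summarize_pd1(diagram: PersistenceDiagram) -> Pd1Summary:
    """Multiplicity-weighted centroid (Center_x, Center_y) and WSS of PD1."""
    if diagram.dimension != 1:
        raise ValueError("expected a dimension-1 diagram")
    coords, weights = _weighted_coords(diagram)
    if len(coords) == 0:
        return Pd1Summary(math.nan, math.nan, math.nan, 0, math.nan)
    center = np.average(coords, axis=0, weights=weights)
    wss = float(((coords - center) ** 2).sum(axis=1) @ weights)
    n = float(weights.sum())
    return Pd1Summary(
        float(center[0]), float(center[1]), wss, int(n), math.sqrt(wss / n)
    )


def bin_diagram(diagram: PersistenceDiagram, grid: int = 32, cap: int = 40) -> BinnedDiagram:
    """Bin diagram multiplicities on a grid×grid lattice over [0, 2^n - 1]^2.

    Cell edges are half-open except the last, so every point lands in
    exactly one cell; `clipped` caps counts at `cap` for rendering with
    a bounded color gradient, `raw` conserves total multiplicity.
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    vmax = 2 ** diagram.bit_depth - 1
    raw = np.zeros((grid, grid), dtype=np.int64)
    for p in diagram.points:
        bi = min(int(p.birth * grid // vmax), grid - 1)
        bj = min(int(p.death * grid // vmax), grid - 1)
        raw[bi, bj] += p.multiplicity
    return BinnedDiagram(raw, np.minimum(raw, cap), grid, cap)


@dataclass(frozen=True)
class ScoreSummary:
    """Full per-image score: PHI, cluster geometry, and PD1 summaries.

    ``status`` is "ok" for a complete score; "insufficient_classes" when
    the filtered PD0 cannot be split in two (the clustering-dependent
    fields are then NaN).
    """

    phi: float
    wss1: float
    wss2: float
    bss: float
    rss: float
    center_x1: float
    center_y1: float
    center_x2: float
    center_y2: float
    pd1_center_x: float
    pd1_center_y: float
    pd1_wss: float
    n_positive: int
    n_negative: int
    n_pd1: int
    wss1_rms: float
    wss2_rms: float
    pd1_wss_rms: float
    delta: int
    status: str = "ok"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


_NAN_CLUSTER_FIELDS = dict(
    phi=math.nan, wss1=math.nan, wss2=math.nan, bss=math.nan, rss=math.nan,
    center_x1=math.nan, center_y1=math.nan, center_x2=math.nan, center_y2=math.nan,
    n_positive=0, n_negative=0,
    wss1_rms=math.nan, wss2_rms=math.nan,
)


def score_image(image: GrayImage, delta: int = 40) -> ScoreSummary:
    """End-to-end score: diagrams -> delta filter -> clustering -> metrics.

    Deterministic for a fixed image and delta.  A PD0 with fewer than
    two distinct classes after filtering yields a structured
    "insufficient_classes" summary rather than an exception; the PD1
    summary is still reported.
    """
    pd0 = filter_noise(compute_pd0(image), delta)
    pd1 = filter_noise(compute_pd1(image), delta)
    s1 = summarize_pd1(pd1)
    pd1_fields = dict(
        pd1_center_x=s1.center_x, pd1_center_y=s1.center_y, pd1_wss=s1.wss,
        n_pd1=s1.n, pd1_wss_rms=s1.wss_rms,
    )
    try:
        clusters = cluster_pd0(pd0)
    except InsufficientClassesError:
        return ScoreSummary(**_NAN_CLUSTER_FIELDS, **pd1_fields, delta=delta,
                            status="insufficient_classes")
    disp = compute_dispersion(clusters)
    return ScoreSummary(
        phi=compute_phi(clusters),
        wss1=disp.wss1, wss2=disp.wss2, bss=disp.bss, rss=disp.rss,
        center_x1=clusters.C1[0], center_y1=clusters.C1[1],
        center_x2=clusters.C2[0], center_y2=clusters.C2[1],
        n_positive=clusters.n_positive, n_negative=clusters.n_negative,
        wss1_rms=disp.wss1_rms, wss2_rms=disp.wss2_rms,
        **pd1_fields, delta=delta,
    )
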