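"""Sublevel-set cubical persistence for grayscale images.

The sublevel sets K_i = f^{-1}([0, i]) of an image f form a growing
sequence K_0 ⊂ K_1 ⊂ ... ⊂ K_{2^n-1}.  Connected components (dimension
0) and holes (dimension 1) appear and disappear along this filtration;
recording each feature's (birth, death) gray levels with multiplicities
gives the persistence diagrams PD0 and PD1.

Pixels are treated as filled unit squares (T-construction): the sublevel
set is 8-connected, its complement 4-connected, and the Euler
characteristic of K_t is V - E + F with vertices/edges present whenever
an incident pixel is.  PD0 is computed by union-find over pixels in
increasing gray order under the elder rule; PD1 by Alexander duality —
union-find on the superlevel (decreasing-gray) filtration with a virtual
"outside" node, so that a hole is born when its enclosed region separates
from the image exterior and dies when the region is absorbed into the
sublevel set.  An independent Betti-number oracle (`betti_at_threshold`)
shares no code with the diagram computation and is used to validate it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "PersistencePoint",
    "PersistenceDiagram",
    "compute_pd0",
    "compute_pd1",
    "betti_at_threshold",
    "persistent_betti",
    "multiplicity",
    "filter_noise",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_OFF8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_OFF4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True, order=True)
class PersistencePoint:
    """A (birth, death) gray-level pair with aggregated multiplicity.

    ``essential`` marks the one dimension-0 class that never merges; its
    death is recorded at the top gray level 2**n - 1 by convention (the
    only case where birth == death is tolerated, on a constant image at
    the top level).
    """

    birth: int
    death: int
    multiplicity: int = 1
    essential: bool = False

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.birth > self.death or (self.birth == self.death and not self.essential):
            raise ValueError(
                f"need birth < death, got ({self.birth}, {self.death})"
            )

    @property
    def persistence(self) -> int:
        return self.death - self.birth


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of persistence points for one homology dimension."""

    dimension: int
    points: tuple[PersistencePoint, ...]
    source_shape: tuple[int, int]  # (X, Y)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.dimension not in (0, 1):
            raise ValueError("only dimensions 0 and 1 are supported")
        object.__setattr__(self, "points", tuple(sorted(self.points)))

    @property
    def total_multiplicity(self) -> int:
        return sum(p.multiplicity for p in self.points)

    def multiplicity_at(self, birth: int, death: int) -> int:
        """Aggregated multiplicity at (birth, death), essential included."""
        return sum(
            p.multiplicity
            for p in self.points
            if p.birth == birth and p.death == death
        )

    def as_weighted_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, 2) array of distinct (birth, death) coordinates and weights."""
        agg: Counter[tuple[int, int]] = Counter()
        for p in self.points:
            agg[(p.birth, p.death)] += p.multiplicity
        if not agg:
            return np.empty((0, 2), dtype=float), np.empty(0, dtype=float)
        coords = np.array(sorted(agg), dtype=float)
        weights = np.array([agg[tuple(c)] for c in coords.astype(int).tolist()], dtype=float)
        return coords, weights

    def to_dataframe(self) -> pd.DataFrame:
        """Documented serialization: one row per distinct (birth, death)."""
        coords, weights = self.as_weighted_array()
        return pd.DataFrame(
            {
                "dimension": self.dimension,
                "birth": coords[:, 0].astype(int),
                "death": coords[:, 1].astype(int),
                "multiplicity": weights.astype(int),
            }
        )


def _aggregate(
    pairs: Iterable[tuple[int, int]],
    essential: Iterable[tuple[int, int]] = (),
) -> list[PersistencePoint]:
    finite = Counter(pairs)
    ess = Counter(essential)
    points = [
        PersistencePoint(b, d, m) for (b, d), m in finite.items()
    ] + [
        PersistencePoint(b, d, m, essential=True) for (b, d), m in ess.items()
    ]
    return points


def _find(parent: list[int], i: int) -> int:
    # path halving
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


def compute_pd0(image: GrayImage) -> PersistenceDiagram:
    """Dimension-0 diagram of the sublevel filtration (elder rule).

    A component is born at the minimum gray level of its basin and dies
    at the level where it merges into an older component (smaller birth;
    ties broken by the earlier row-major minimum pixel).  The one
    component that never merges is recorded as essential with death at
    the top gray level.
    """
    pix = image.pixels
    Y, X = pix.shape
    vmax = image.max_value
    vals = pix.ravel().tolist()
    order = np.argsort(pix.ravel(), kind="stable").tolist()

    n = Y * X
    parent = [-1] * n
    birth = [0] * n
    anchor = [0] * n
    pairs: list[tuple[int, int]] = []

    for idx in order:
        v = vals[idx]
        parent[idx] = idx
        birth[idx] = v
        anchor[idx] = idx
        r, c = divmod(idx, X)
        for dr, dc in _OFF8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < Y and 0 <= cc < X:
                j = rr * X + cc
                if parent[j] >= 0:
                    ra = _find(parent, idx)
                    rb = _find(parent, j)
                    if ra == rb:
                        continue
                    # elder rule: smaller birth survives; tie -> earlier minimum pixel
                    if (birth[rb], anchor[rb]) < (birth[ra], anchor[ra]):
                        ra, rb = rb, ra
                    if birth[rb] < v:
                        pairs.append((birth[rb], v))
                    parent[rb] = ra

    root = _find(parent, order[0])
    essential = [(birth[root], vmax)]
    return PersistenceDiagram(0, tuple(_aggregate(pairs, essential)), (X, Y), image.bit_depth)


def compute_pd1(image: GrayImage) -> PersistenceDiagram:
    """Dimension-1 diagram of the sublevel filtration, via duality.

    Holes of the 8-connected sublevel set correspond to bounded
    4-connected components of the strict superlevel set.  Union-find on
    pixels in decreasing gray order, with a virtual node for the image
    exterior, pairs each enclosed region's separation level (hole birth)
    with its maximum gray value (hole death).  On a full rectangular
    image no hole survives the top level, so PD1 has no essential class.
    """
    pix = image.pixels
    Y, X = pix.shape
    vals = pix.ravel().tolist()
    order = np.argsort(-pix.ravel(), kind="stable").tolist()

    n = Y * X
    out = n  # virtual exterior node, elder than everything
    parent = [-1] * n + [out]
    birth = [0] * n + [image.max_value + 1]
    anchor = [0] * n + [-1]
    pairs: list[tuple[int, int]] = []

    def merge(a: int, b: int, level: int) -> None:
        ra, rb = _find(parent, a), _find(parent, b)
        if ra == rb:
            return
        # elder rule on the superlevel side: larger maximum survives
        if (birth[rb], -anchor[rb]) > (birth[ra], -anchor[ra]):
            ra, rb = rb, ra
        if level < birth[rb]:
            pairs.append((level, birth[rb]))  # hole: born at merge level, dies at region max
        parent[rb] = ra

    for idx in order:
        v = vals[idx]
        parent[idx] = idx
        birth[idx] = v
        anchor[idx] = idx
        r, c = divmod(idx, X)
        for dr, dc in _OFF4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < Y and 0 <= cc < X:
                j = rr * X + cc
                if parent[j] >= 0:
                    merge(idx, j, v)
            else:
                merge(idx, out, v)

    return PersistenceDiagram(1, tuple(_aggregate(pairs)), (X, Y), image.bit_depth)


def betti_at_threshold(image: GrayImage, t: int) -> tuple[int, int]:
    """Independent (β0, β1) oracle for the sublevel set K_t.

    β0 by 8-connected labeling of the binary mask; β1 = β0 - χ with the
    Euler characteristic χ = V - E + F of the filled-square complex
    (a vertex or edge is present when any incident pixel is in the mask).
    Shares no code with the diagram computation.
    """
    if not (0 <= t <= image.max_value):
        raise ValueError(f"threshold {t} outside [0, {image.max_value}]")
    mask = image.pixels <= t
    if not mask.any():
        return 0, 0
    _, b0 = ndimage.label(mask, structure=_STRUCT8)

    pad = np.pad(mask, 1)
    Y, X = mask.shape
    faces = int(mask.sum())
    verts = int(
        (pad[0:Y + 1, 0:X + 1] | pad[0:Y + 1, 1:X + 2]
         | pad[1:Y + 2, 0:X + 1] | pad[1:Y + 2, 1:X + 2]).sum()
    )
    h_edges = int((pad[0:Y + 1, 1:X + 1] | pad[1:Y + 2, 1:X + 1]).sum())
    v_edges = int((pad[1:Y + 1, 0:X + 1] | pad[1:Y + 1, 1:X + 2]).sum())
    chi = verts - (h_edges + v_edges) + faces
    return int(b0), int(b0) - chi


def _alive_count(
    diagram: PersistenceDiagram, i: int, j: int, *, immortal_essential: bool
) -> int:
    """Classes born ≤ i and alive after level j.

    With ``immortal_essential`` the essential class counts for every j
    once born (the rank of H(K_i) -> H(K_j)); without it, its recorded
    death at the top level is taken literally, which is the finite-
    filtration convention under which the inclusion–exclusion formula
    reproduces the diagram's stored multiplicities at the top level.
    """
    if i < 0:
        return 0
    total = 0
    for p in diagram.points:
        if p.birth <= i and (p.death > j or (immortal_essential and p.essential)):
            total += p.multiplicity
    return total


def _diagram_for(image: GrayImage, p: int, diagram: PersistenceDiagram | None) -> PersistenceDiagram:
    if diagram is not None:
        if diagram.dimension != p:
            raise ValueError(f"diagram has dimension {diagram.dimension}, expected {p}")
        return diagram
    return compute_pd0(image) if p == 0 else compute_pd1(image)


def persistent_betti(
    image: GrayImage,
    p: int,
    i: int,
    j: int,
    *,
    diagram: PersistenceDiagram | None = None,
) -> int:
    """Persistent Betti number β_p^{i,j}: rank of H_p(K_i) -> H_p(K_j).

    Counted from the diagram as classes with birth ≤ i and death > j,
    plus essential classes born by i.  Pass a precomputed ``diagram`` to
    avoid recomputation in loops.
    """
    if i > j:
        raise ValueError(f"need i <= j, got ({i}, {j})")
    if not (0 <= i and j <= image.max_value):
        raise ValueError(f"(i, j) = ({i}, {j}) outside [0, {image.max_value}]")
    dgm = _diagram_for(image, p, diagram)
    return _alive_count(dgm, i, j, immortal_essential=True)


def multiplicity(
    image: GrayImage,
    p: int,
    i: int,
    j: int,
    *,
    diagram: PersistenceDiagram | None = None,
) -> int:
    """Multiplicity μ_p^{i,j} by inclusion–exclusion over persistent Betti
    numbers:

        μ_p^{i,j} = β_p^{i,j-1} - β_p^{i-1,j-1} - (β_p^{i,j} - β_p^{i-1,j})

    with boundary terms at index -1 defined as 0 (K_{-1} is empty).  The
    counts treat the essential class's recorded death at the top gray
    level literally, so the formula agrees with the stored diagram
    multiplicity at every point including survivors plotted at the top.
    """
    if not (0 <= i < j <= image.max_value):
        raise ValueError(f"need 0 <= i < j <= {image.max_value}, got ({i}, {j})")
    dgm = _diagram_for(image, p, diagram)

    def beta(a: int, b: int) -> int:
        return _alive_count(dgm, a, b, immortal_essential=False)

    return beta(i, j - 1) - beta(i - 1, j - 1) - (beta(i, j) - beta(i - 1, j))


def filter_noise(diagram: PersistenceDiagram, delta: int) -> PersistenceDiagram:
    """Drop short-lived classes: keep points with death - birth >= delta.

    Points with persistence below delta are topological noise artifacts;
    multiplicities of surviving points are preserved and the input is
    left unmodified.  delta = 0 returns the diagram unchanged.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    kept = tuple(p for p in diagram.points if p.persistence >= delta)
    return PersistenceDiagram(
        diagram.dimension, kept, diagram.source_shape, diagram.bit_depth
    )
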