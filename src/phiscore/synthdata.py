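"""Synthetic images with known topological ground truth.

Two generators:

* ``make_fixture`` builds tiny three-gray-level block images whose
  persistence diagrams are known exactly by construction — a components
  layout (dark blocks, some bridged at the middle level, plus isolated
  mid-gray blocks) and a holes layout (rings whose interiors are one
  level brighter).  Intended adjacencies are all edge-sharing and
  intended separations are at least 2 pixels, so the diagrams are the
  same under 4- and 8-connectivity conventions.

* ``make_ihc_image`` emulates a Ki-67-stained field: dark "positive"
  nuclei and mid-gray "negative" nuclei as non-overlapping axis-aligned
  ellipses on a bright background, with additive Gaussian noise.  The
  per-nucleus ground truth (center, axes, class) is returned alongside,
  so index recovery can be checked against a known positive fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .image import GrayImage

__all__ = [
    "FixtureSpec",
    "SyntheticParams",
    "Nucleus",
    "IHCGroundTruth",
    "make_fixture",
    "make_ihc_image",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Layout controls for the three-level topology fixtures.

    kind="components": on an H background, 3 isolated dark (L) blocks,
    2 dark blocks each joined to a distinct dark block by an M bridge,
    and 5 isolated mid-gray (M) blocks.  PD0 is exactly
    {(L,M): 2, (L,H): 3, (M,H): 5}.

    kind="holes": 2 L rings with M interiors and 2 M rings with H
    interiors.  PD1 is exactly {(L,M): 2, (M,H): 2}.
    """

    kind: str = "components"
    levels: tuple[int, int, int] = (0, 128, 255)
    canvas: tuple[int, int] = (56, 24)  # (X, Y)
    block_size: int = 4

    def __post_init__(self) -> None:
        low, mid, high = self.levels
        if not (0 <= low < mid < high <= 255):
            raise ValueError(f"need 0 <= L < M < H <= 255, got {self.levels}")
        if self.kind not in ("components", "holes"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


_GAP = 3          # separation between structures (>= 2 keeps them apart under 8-connectivity)
_BRIDGE_W = 3     # horizontal extent of the mid-level bridge between paired dark blocks
_RING_THICK = 2   # ring wall thickness (>= 2: no diagonal leaks through the wall)
_RING_HOLE = 3    # interior side length


def _required_canvas(spec: FixtureSpec) -> tuple[int, int]:
    b, g = spec.block_size, _GAP
    if spec.kind == "components":
        # row 1: [pair][pair][block], row 2: five blocks
        row1 = 2 * (2 * b + _BRIDGE_W) + b + 4 * g  # margins + two pairs + lone block
        row2 = 5 * b + 6 * g                        # margins + five blocks
        return (max(row1, row2), 2 * b + 3 * g)
    ring = _RING_HOLE + 2 * _RING_THICK
    return (4 * ring + 5 * g, ring + 2 * g)


def make_fixture(spec: FixtureSpec = FixtureSpec()) -> GrayImage:
    """Render a three-level topology fixture as a GrayImage."""
    low, mid, high = spec.levels
    X, Y = spec.canvas
    need_x, need_y = _required_canvas(spec)
    if X < need_x or Y < need_y:
        raise ValueError(
            f"canvas {spec.canvas} too small for kind={spec.kind!r}; "
            f"need at least ({need_x}, {need_y})"
        )
    img = np.full((Y, X), high, dtype=np.int64)
    b, g = spec.block_size, _GAP

    if spec.kind == "components":
        y1 = g  # top of row 1
        x = g
        # two (dark block)-(M bridge)-(dark block) pairs
        for _ in range(2):
            img[y1:y1 + b, x:x + b] = low
            ymid = y1 + (b - 2) // 2
            img[ymid:ymid + 2, x + b:x + b + _BRIDGE_W] = mid
            img[y1:y1 + b, x + b + _BRIDGE_W:x + 2 * b + _BRIDGE_W] = low
            x += 2 * b + _BRIDGE_W + g
        # third persistent dark block
        img[y1:y1 + b, x:x + b] = low
        # row 2: five isolated mid-gray blocks
        y2 = y1 + b + g
        x = g
        for _ in range(5):
            img[y2:y2 + b, x:x + b] = mid
            x += b + g
    else:
        ring = _RING_HOLE + 2 * _RING_THICK
        y0 = g
        x = g
        for wall, interior in ((low, mid), (low, mid), (mid, high), (mid, high)):
            img[y0:y0 + ring, x:x + ring] = wall
            t = _RING_THICK
            img[y0 + t:y0 + ring - t, x + t:x + ring - t] = interior
            x += ring + g
    return GrayImage(img)


@dataclass(frozen=True)
class SyntheticParams:
    """Controls for the IHC-like field generator.

    Defaults emulate a ×40 Ki-67 field at reduced canvas size: dark
    positive nuclei (gray ~30), lighter negative nuclei (~130), bright
    background (~220), mild additive noise.
    """

    canvas: tuple[int, int] = (256, 256)  # (X, Y)
    n_nuclei: int = 40
    positive_fraction: float = 0.5
    radius_mean: float = 6.0
    radius_sd: float = 1.5
    positive_gray: int = 30
    negative_gray: int = 130
    background_gray: int = 220
    noise_sd: float = 5.0
    min_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.positive_fraction <= 1):
            raise ValueError("positive_fraction must be in [0, 1]")
        if not (0 <= self.positive_gray < self.negative_gray < self.background_gray <= 255):
            raise ValueError("need 0 <= positive_gray < negative_gray < background_gray <= 255")
        if self.n_nuclei < 0 or self.radius_mean <= 0 or self.noise_sd < 0:
            raise ValueError("invalid generator parameters")


@dataclass(frozen=True)
class Nucleus:
    center: tuple[float, float]  # (x, y)
    axes: tuple[float, float]    # semi-axes (a, b)
    label: str                   # "positive" | "negative"


@dataclass(frozen=True)
class IHCGroundTruth:
    nuclei: tuple[Nucleus, ...]
    n_positive: int
    n_negative: int
    params: SyntheticParams

    def to_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "params": asdict(self.params),
            "nuclei": [asdict(n) for n in self.nuclei],
        }


_MAX_ATTEMPTS = 10_000


def make_ihc_image(params: SyntheticParams = SyntheticParams()) -> tuple[GrayImage, IHCGroundTruth]:
    """Generate an IHC-like field and its ground truth.

    Non-overlapping axis-aligned ellipses are placed by rejection
    sampling (centers uniform; semi-axes Gaussian, truncated at 2 px;
    separation enforced on bounding circles).  Positives are filled at
    ``positive_gray``, negatives at ``negative_gray``; Gaussian noise of
    ``noise_sd`` gray levels is added, clipped to [0, 255] and rounded.
    The same seed reproduces the identical image.
    """
    rng = np.random.default_rng(params.seed)
    X, Y = params.canvas
    n_pos = round(params.n_nuclei * params.positive_fraction)
    labels = ["positive"] * n_pos + ["negative"] * (params.n_nuclei - n_pos)

    placed: list[Nucleus] = []
    for label in labels:
        for attempt in range(_MAX_ATTEMPTS):
            a, b = np.maximum(
                rng.normal(params.radius_mean, params.radius_sd, size=2), 2.0
            )
            r = max(a, b)
            if 2 * r + 2 >= min(X, Y):
                continue
            cx = rng.uniform(r + 1, X - r - 1)
            cy = rng.uniform(r + 1, Y - r - 1)
            ok = all(
                np.hypot(cx - n.center[0], cy - n.center[1])
                >= r + max(n.axes) + params.min_separation
                for n in placed
            )
            if ok:
                placed.append(Nucleus((cx, cy), (float(a), float(b)), label))
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(placed) + 1}/{params.n_nuclei} "
                f"after {_MAX_ATTEMPTS} attempts; placed {len(placed)}"
            )

    img = np.full((Y, X), float(params.background_gray))
    yy, xx = np.mgrid[0:Y, 0:X]
    for n in placed:
        a, b = n.axes
        cx, cy = n.center
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        img[mask] = params.positive_gray if n.label == "positive" else params.negative_gray

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.int64)

    truth = IHCGroundTruth(tuple(placed), n_pos, params.n_nuclei - n_pos, params)
    return GrayImage(img), truth
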