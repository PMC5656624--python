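"""Diagram computation against worked examples and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from phiscore import (
    GrayImage,
    PersistenceDiagram,
    PersistencePoint,
    betti_at_threshold,
    compute_pd0,
    compute_pd1,
    filter_noise,
    multiplicity,
    persistent_betti,
)

L, M, H = 0, 128, 255


def diagram_multiset(diagram):
    """Collapse a diagram to {(birth, death): total multiplicity}."""
    out = {}
    for p in diagram.points:
        key = (p.birth, p.death)
        out[key] = out.get(key, 0) + p.multiplicity
    return out


def alive_count(diagram, t):
    """Classes alive at threshold t (essential classes stay alive once born)."""
    return sum(
        p.multiplicity
        for p in diagram.points
        if (p.birth <= t < p.death) or (p.essential and p.birth <= t)
    )


small_images = arrays(np.int64, (12, 12), elements=st.integers(0, 7))


class TestPD0:
    def test_components_fixture_multiset(self, components_image):
        """Bridged dark blocks die at M, three survive to H, five mid-gray appear at M."""
        assert diagram_multiset(compute_pd0(components_image)) == {
            (L, M): 2,
            (L, H): 3,
            (M, H): 5,
        }

    def test_constant_image_single_essential_class(self):
        dgm = compute_pd0(GrayImage(np.full((6, 9), 17)))
        assert [(p.birth, p.death, p.multiplicity, p.essential) for p in dgm.points] == [
            (17, 255, 1, True)
        ]

    @pytest.mark.parametrize(
        "bad",
        [np.empty((0, 4), dtype=int), np.array([[0.5, 1.0]]), np.array([[-1, 3]]), np.array([[0, 256]])],
        ids=["empty", "fractional", "negative", "overflow"],
    )
    def test_invalid_images_rejected(self, bad):
        with pytest.raises(ValueError):
            GrayImage(bad)

    def test_one_pixel_wide_image_is_legal(self):
        col = GrayImage(np.array([[3], [1], [4], [1]]))
        assert compute_pd0(col).total_multiplicity == 2  # two basins at value 1
        assert compute_pd1(col).points == ()

    def test_random_images_match_component_oracle(self, rng):
        """Alive-class counts at every threshold equal direct labeling."""
        for _ in range(50):
            img = GrayImage(rng.integers(0, 8, size=(12, 12)))
            dgm = compute_pd0(img)
            for t in range(8):
                b0, _b1 = betti_at_threshold(img, t)
                assert alive_count(dgm, t) == b0


class TestPD1:
    def test_holes_fixture_multiset(self, holes_image):
        """Dark rings fill at M; mid-gray rings appear at M and fill at H."""
        assert diagram_multiset(compute_pd1(holes_image)) == {(L, M): 2, (M, H): 2}

    def test_monotone_gradient_has_no_holes(self):
        img = GrayImage(np.tile(np.arange(20), (8, 1)))
        assert compute_pd1(img).points == ()

    def test_random_images_match_euler_oracle(self, rng):
        for _ in range(50):
            img = GrayImage(rng.integers(0, 8, size=(12, 12)))
            dgm = compute_pd1(img)
            for t in range(8):
                _b0, b1 = betti_at_threshold(img, t)
                assert alive_count(dgm, t) == b1


class TestBettiOracle:
    def test_components_fixture_at_medium_level(self, components_image):
        """Three merged dark domains plus five newly appeared mid-gray blocks."""
        assert betti_at_threshold(components_image, M) == (8, 0)

    def test_empty_sublevel_set(self):
        img = GrayImage(np.full((5, 5), 200))
        assert betti_at_threshold(img, 100) == (0, 0)

    def test_ring_has_one_component_one_hole(self):
        arr = np.zeros((3, 3), dtype=int)
        arr[1, 1] = 255
        assert betti_at_threshold(GrayImage(arr), 0) == (1, 1)

    def test_threshold_out_of_range_rejected(self, components_image):
        with pytest.raises(ValueError):
            betti_at_threshold(components_image, 256)


def brute_containment_count(img, i, j):
    """Components of K_j that contain at least one component of K_i."""
    struct = np.ones((3, 3))
    li, ni = ndimage.label(img.pixels <= i, structure=struct)
    lj, _ = ndimage.label(img.pixels <= j, structure=struct)
    if ni == 0:
        return 0
    return len({lj[tuple(np.argwhere(li == k)[0])] for k in range(1, ni + 1)})


class TestPersistentBetti:
    def test_fixture_dark_blocks_surviving_to_medium(self, components_image):
        assert persistent_betti(components_image, 0, L, M) == 3

    @pytest.mark.parametrize("p", [0, 1])
    def test_identity_map_gives_betti_number(self, components_image, p):
        dgm = compute_pd0(components_image) if p == 0 else compute_pd1(components_image)
        for t in (L, M, 200, H):
            expected = betti_at_threshold(components_image, t)[p]
            assert persistent_betti(components_image, p, t, t, diagram=dgm) == expected

    def test_matches_label_containment_brute_force(self, rng):
        for _ in range(30):
            img = GrayImage(rng.integers(0, 8, size=(10, 10)))
            dgm = compute_pd0(img)
            for i in range(8):
                for j in range(i, 8):
                    assert (
                        persistent_betti(img, 0, i, j, diagram=dgm)
                        == brute_containment_count(img, i, j)
                    )

    def test_reversed_levels_rejected(self, components_image):
        with pytest.raises(ValueError):
            persistent_betti(components_image, 0, 10, 5)


class TestMultiplicityFormula:
    def test_fixture_mid_gray_blocks(self, components_image):
        assert multiplicity(components_image, 0, M, H) == 5

    def test_unoccupied_point_is_zero(self, components_image):
        dgm = compute_pd0(components_image)
        assert multiplicity(components_image, 0, 3, 77, diagram=dgm) == 0

    @pytest.mark.parametrize("p", [0, 1])
    def test_formula_equals_stored_multiplicity(self, rng, p):
        """Inclusion–exclusion over persistent Betti numbers reproduces the diagram."""
        for _ in range(10):
            img = GrayImage(rng.integers(0, 256, size=(8, 8)))
            dgm = compute_pd0(img) if p == 0 else compute_pd1(img)
            for pt in dgm.points:
                assert (
                    multiplicity(img, p, pt.birth, pt.death, diagram=dgm)
                    == dgm.multiplicity_at(pt.birth, pt.death)
                )


class TestFilterNoise:
    def make(self, spec):
        pts = tuple(PersistencePoint(b, d, m) for (b, d), m in spec.items())
        return PersistenceDiagram(0, pts, (4, 4))

    def test_short_bars_removed(self):
        dgm = self.make({(10, 30): 4, (10, 200): 1})
        assert diagram_multiset(filter_noise(dgm, 40)) == {(10, 200): 1}

    def test_zero_delta_is_identity(self):
        dgm = self.make({(10, 30): 4, (10, 200): 1})
        assert filter_noise(dgm, 0).points == dgm.points

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            filter_noise(self.make({(0, 9): 1}), -1)

    @given(st.lists(st.tuples(st.integers(0, 254), st.integers(1, 255)), min_size=1, max_size=20),
           st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_conservation_and_delta_composition(self, raw, d1, d2):
        pts = tuple(PersistencePoint(b, max(b + 1, d)) for b, d in raw)
        dgm = PersistenceDiagram(0, pts, (4, 4))
        kept = filter_noise(dgm, d1)
        removed = sum(p.multiplicity for p in dgm.points if p.persistence < d1)
        assert kept.total_multiplicity + removed == dgm.total_multiplicity
        # composing filters equals filtering at the larger delta; idempotent
        assert filter_noise(kept, d2).points == filter_noise(dgm, max(d1, d2)).points
        assert filter_noise(kept, d1).points == kept.points


@given(arrays(np.int64, (6, 6), elements=st.integers(0, 150)), st.integers(1, 100))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_gray_shift_equivariance(arr, c):
    """Adding a constant to all pixels shifts every birth and death by it."""
    base = GrayImage(arr)
    shifted = GrayImage(arr + c)
    for compute in (compute_pd0, compute_pd1):
        a = diagram_multiset(compute(base))
        b = diagram_multiset(compute(shifted))
        # the essential death is pinned at the top gray level, not shifted
        a_fin = {k: v for k, v in a.items() if k[1] != 255}
        b_fin = {k: v for k, v in b.items() if k[1] != 255}
        assert {(bb + c, dd + c): m for (bb, dd), m in a_fin.items()} == b_fin


def test_essential_birth_shifts_with_gray_offset():
    arr = np.array([[5, 9], [9, 5]])
    for c in (0, 30):
        dgm = compute_pd0(GrayImage(arr + c))
        ess = [p for p in dgm.points if p.essential]
        assert len(ess) == 1 and ess[0].birth == 5 + c and ess[0].death == 255
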