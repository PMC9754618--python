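"""Double-mapping scanpath distance: examples, properties, oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scanpath3d.errors import ValidationError
from scanpath3d.eyenalysis import (
    ConversionFactor,
    DistanceMatrix,
    compute_conversion_factor,
    divergence_summary,
    double_map_distance,
    pairwise_matrix,
    point_distance,
    sculpture_distance,
    sculpture_distance_detail,
    to_points3,
)
from scanpath3d.expertise import ExpertiseLevel, ExpertiseProfile
from scanpath3d.io import format_distance


def brute_double_map(S, T):
    """Independent O(|S|*|T|) enumeration of the double-mapping distance."""
    def nearest(p, pts):
        return min(math.dist(p, q) for q in pts)

    total = sum(nearest(p, T) for p in S) + sum(nearest(q, S) for q in T)
    return total / max(len(S), len(T))


UNIT_FACTOR = ConversionFactor("moses", 1.0, "configured")


class TestPointDistance:
    def test_identity(self):
        assert point_distance((1, 2, 3), (1, 2, 3)) == 0.0

    def test_3_4_5_triangle(self):
        assert point_distance((0, 0, 0), (3, 4, 0)) == 5.0

    def test_hand_computed(self):
        assert point_distance((1, 2, 2), (0, 0, 0)) == pytest.approx(3.0)


class TestDoubleMap:
    def test_identical_sets_zero(self, rng):
        S = rng.uniform(0, 100, size=(7, 3))
        assert double_map_distance(S, S) == 0.0

    def test_singletons(self):
        assert double_map_distance([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(10.0)

    def test_translation_gives_twice_delta(self):
        # points spaced 100 apart; translation well below half the spacing
        S = np.array([[0.0, 0, 0], [100, 0, 0], [200, 0, 0]])
        delta = 7.0
        T = S + np.array([delta, 0, 0])
        assert double_map_distance(S, T) == pytest.approx(2 * delta)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            double_map_distance(np.empty((0, 3)), [[1, 2, 3]])

    def test_symmetry_and_oracle_random_instances(self, rng):
        for _ in range(20):
            S = rng.uniform(0, 500, size=(int(rng.integers(1, 50)), 3))
            T = rng.uniform(0, 500, size=(int(rng.integers(1, 50)), 3))
            d = double_map_distance(S, T)
            assert d == pytest.approx(double_map_distance(T, S), rel=1e-12)
            assert d == pytest.approx(brute_double_map(S.tolist(), T.tolist()), rel=1e-9)

    @given(st.integers(min_value=1, max_value=15), st.integers(min_value=1, max_value=15),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_nonnegative_and_symmetric(self, n, m, seed):
        gen = np.random.default_rng(seed)
        S = gen.normal(size=(n, 3))
        T = gen.normal(size=(m, 3))
        d = double_map_distance(S, T)
        assert d >= 0
        assert d == pytest.approx(double_map_distance(T, S), rel=1e-12)


class TestConversionFactor:
    def test_height_over_max_duration(self, make_scanpath):
        paths = [make_scanpath([100, 500]), make_scanpath([250], participant="p2")]
        factor = compute_conversion_factor(paths, 1000)
        assert factor.value == pytest.approx(2.0)
        assert factor.source == "computed"

    def test_unit_case(self, make_scanpath):
        assert compute_conversion_factor([make_scanpath([700])], 700).value == 1.0

    def test_doubling_durations_halves_factor(self, make_scanpath):
        a = [make_scanpath([100, 400])]
        b = [make_scanpath([200, 800])]
        fa = compute_conversion_factor(a, 1000)
        fb = compute_conversion_factor(b, 1000)
        assert fb.value == pytest.approx(fa.value / 2)
        # scaled z of the longest fixation is unchanged (= sculpture height)
        assert 400 * fa.value == pytest.approx(800 * fb.value) == 1000

    def test_no_fixations_rejected(self, make_scanpath):
        with pytest.raises(ValidationError):
            compute_conversion_factor([make_scanpath([])], 1000)

    def test_mixed_sculptures_rejected(self, make_scanpath):
        paths = [make_scanpath([100]), make_scanpath([100], sculpture="daphne")]
        with pytest.raises(ValidationError):
            compute_conversion_factor(paths, 1000)

    @pytest.mark.parametrize("value", [1.097, 1.731])
    def test_published_overrides_accepted(self, value):
        assert ConversionFactor("m", value, "configured").value == value

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            ConversionFactor("m", 0.0, "configured")


class TestSculptureDistance:
    def test_self_distance_zero(self, make_scanpath):
        sp = make_scanpath([100, 300, 200], xs=[1, 50, 90], ys=[5, 60, 10],
                           ref_images=[1, 2, 2])
        assert sculpture_distance(sp, sp, UNIT_FACTOR) == 0.0

    def test_unshared_image_skipped(self, make_scanpath):
        # identical single fixations on images 1 and 2; A alone on image 3
        a = make_scanpath([100, 100, 100], xs=[10, 20, 99], ys=[10, 20, 99],
                          ref_images=[1, 2, 3])
        b = make_scanpath([100, 100], xs=[10, 20], ys=[10, 20],
                          ref_images=[1, 2], participant="p2")
        detail = sculpture_distance_detail(a, b, UNIT_FACTOR)
        assert detail.value == 0.0
        assert detail.n_images_used == 2
        assert detail.n_images_skipped == 1

    def test_single_shared_image_reduces_to_double_map(self, make_scanpath):
        a = make_scanpath([100], xs=[0], ys=[0])
        b = make_scanpath([100], xs=[3], ys=[4], participant="p2")
        assert sculpture_distance(a, b, UNIT_FACTOR) == pytest.approx(10.0)

    def test_no_shared_image_undefined(self, make_scanpath):
        a = make_scanpath([100], ref_images=[1])
        b = make_scanpath([100], ref_images=[2], participant="p2")
        with pytest.warns(UserWarning, match="no shared reference image"):
            assert math.isnan(sculpture_distance(a, b, UNIT_FACTOR))

    def test_different_sculptures_rejected(self, make_scanpath):
        a = make_scanpath([100])
        b = make_scanpath([100], sculpture="daphne", participant="p2")
        with pytest.raises(ValidationError):
            sculpture_distance(a, b, UNIT_FACTOR)

    def test_scale_consistency(self, make_scanpath, rng):
        """Multiplying durations by c and dividing the factor by c leaves
        every distance unchanged (the z axis is the invariant product)."""
        dur_a = rng.uniform(50, 800, 12)
        dur_b = rng.uniform(50, 800, 9)
        kwargs = dict(xs=None, ys=None)
        imgs_a = list(rng.integers(1, 4, 12))
        imgs_b = list(rng.integers(1, 4, 9))
        xa, ya = rng.uniform(0, 300, 12), rng.uniform(0, 300, 12)
        xb, yb = rng.uniform(0, 300, 9), rng.uniform(0, 300, 9)
        c = 3.7
        a1 = make_scanpath(dur_a, xs=xa, ys=ya, ref_images=imgs_a)
        b1 = make_scanpath(dur_b, xs=xb, ys=yb, ref_images=imgs_b, participant="p2")
        a2 = make_scanpath(dur_a * c, xs=xa, ys=ya, ref_images=imgs_a)
        b2 = make_scanpath(dur_b * c, xs=xb, ys=yb, ref_images=imgs_b, participant="p2")
        f1 = ConversionFactor("moses", 0.9, "configured")
        f2 = ConversionFactor("moses", 0.9 / c, "configured")
        assert sculpture_distance(a1, b1, f1) == pytest.approx(
            sculpture_distance(a2, b2, f2), rel=1e-12
        )

    def test_points_preserve_order_and_scale(self, make_scanpath):
        sp = make_scanpath([100, 200], xs=[1, 2], ys=[3, 4], ref_images=[2, 2])
        pts = to_points3(sp, ConversionFactor("moses", 0.5, "configured"))
        assert np.allclose(pts[2], [[1, 3, 50], [2, 4, 100]])


def _cohort_profiles(n_per_level=5):
    out = {}
    i = 0
    for level in ExpertiseLevel:
        for _ in range(n_per_level):
            pid = f"p{i:02d}"
            out[pid] = ExpertiseProfile(pid, float(level), level)
            i += 1
    return out


class TestPairwiseMatrix:
    def test_two_identical_participants(self, make_scanpath):
        a = make_scanpath([100, 200], xs=[0, 10], ys=[0, 10], participant="p00")
        b = make_scanpath([100, 200], xs=[0, 10], ys=[0, 10], participant="p01")
        profiles = {
            "p00": ExpertiseProfile("p00", 0.0, ExpertiseLevel.LAYPERSON),
            "p01": ExpertiseProfile("p01", 0.0, ExpertiseLevel.LAYPERSON),
        }
        matrix = pairwise_matrix([a, b], profiles, UNIT_FACTOR)
        assert np.array_equal(matrix.values, np.zeros((2, 2)))

    def test_matches_independent_pair_calls(self, make_scanpath, rng):
        paths = []
        profiles = {}
        for i, level in enumerate([ExpertiseLevel.LAYPERSON, ExpertiseLevel.NOVICE,
                                   ExpertiseLevel.EXPERT]):
            pid = f"p{i}"
            paths.append(
                make_scanpath(
                    rng.uniform(50, 600, 8),
                    xs=rng.uniform(0, 300, 8),
                    ys=rng.uniform(0, 300, 8),
                    ref_images=list(rng.integers(1, 4, 8)),
                    participant=pid,
                )
            )
            profiles[pid] = ExpertiseProfile(pid, float(level), level)
        matrix = pairwise_matrix(paths, profiles, UNIT_FACTOR)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.all(np.diag(matrix.values) == 0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert matrix.values[i, j] == pytest.approx(
                    sculpture_distance(paths[i], paths[j], UNIT_FACTOR)
                )
        assert matrix.divergence[0, 2] == 3


def _matrix_with_group_constants(cell_means, n_per_level=5):
    """DistanceMatrix whose every pair distance equals its (level_a, level_b)
    cell value; pooled divergence means are then exactly predictable."""
    profiles = _cohort_profiles(n_per_level)
    ids = sorted(profiles)
    n = len(ids)
    values = np.zeros((n, n))
    divergence = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            la, lb = int(profiles[ids[i]].level), int(profiles[ids[j]].level)
            values[i, j] = cell_means[(min(la, lb), max(la, lb))]
            divergence[i, j] = abs(la - lb)
    return DistanceMatrix("moses", ids, values, divergence)


class TestDivergenceSummary:
    # published per-cell mean distances (px) for the first sculpture
    CELLS = {
        (0, 0): 1372, (1, 1): 6410, (2, 2): 8483, (3, 3): 4961,
        (0, 1): 8479, (1, 2): 6632, (2, 3): 6365,
        (0, 2): 9434, (1, 3): 5246,
        (0, 3): 7660,
    }

    def test_pooled_means_match_cell_aggregation(self):
        """Equal per-cell pair counts make the pooled divergence means the
        plain means of the constituent cell means: 5306.5, 7158.67, 7340,
        7660 — printed as 5307/7159/7340/7660 under half-up rounding."""
        matrix = _matrix_with_group_constants(self.CELLS)
        summary = divergence_summary(matrix).set_index("divergence")
        assert list(summary["n"]) == [40, 75, 50, 25]
        assert summary.loc[0, "mean"] == pytest.approx((1372 + 6410 + 8483 + 4961) / 4)
        assert summary.loc[1, "mean"] == pytest.approx((8479 + 6632 + 6365) / 3)
        assert summary.loc[2, "mean"] == pytest.approx((9434 + 5246) / 2)
        assert summary.loc[3, "mean"] == pytest.approx(7660)
        assert format_distance(summary.loc[0, "mean"]) == "5307"

    def test_self_pairs_excluded(self):
        matrix = _matrix_with_group_constants(self.CELLS)
        total_pairs = divergence_summary(matrix)["n"].sum()
        assert total_pairs == 20 * 19 // 2  # diagonal removed

    def test_missing_cell_dropped_with_warning(self):
        matrix = _matrix_with_group_constants(self.CELLS)
        matrix.values[0, 1] = matrix.values[1, 0] = math.nan
        with pytest.warns(UserWarning, match="undefined"):
            summary = divergence_summary(matrix).set_index("divergence")
        assert summary.loc[0, "n"] == 39

    def test_single_pair_sd_degenerate(self):
        profiles = _cohort_profiles(1)
        ids = sorted(profiles)
        values = np.ones((4, 4)) - np.eye(4)
        divergence = np.abs(np.subtract.outer(range(4), range(4)))
        matrix = DistanceMatrix("m", ids, values, np.asarray(divergence))
        with pytest.warns(UserWarning, match="degenerate"):
            summary = divergence_summary(matrix).set_index("divergence")
        assert bool(summary.loc[3, "sd_degenerate"])
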