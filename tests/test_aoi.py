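"""AOI hit testing, coverage metrics and the revisit state machine."""

import math
from itertools import product

import pytest

from scanpath3d.aoi import (
    hit_test,
    n_features_fixated,
    pct_on_features,
    revisit_count,
    revisits_per_minute,
    visit_runs,
)
from scanpath3d.errors import ValidationError
from scanpath3d.io import AOIRegion, AOISet


def even_odd_contains(x, y, vertices):
    """Independent even-odd (ray casting) point-in-polygon oracle."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def square(feature, img, x0, y0, size):
    return AOIRegion(
        feature, img,
        ((x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)),
    )


@pytest.fixture
def simple_aois():
    return AOISet("moses", [square("head", 1, 0, 0, 10), square("hand", 1, 50, 50, 10)])


class TestHitTest:
    def test_centroid_hit(self, make_scanpath, simple_aois):
        sp = make_scanpath([100], xs=[5], ys=[5])
        assert hit_test(sp, simple_aois).hits == ("head",)

    def test_vertex_hit_boundary_inclusive(self, make_scanpath, simple_aois):
        sp = make_scanpath([100], xs=[50], ys=[50])
        assert hit_test(sp, simple_aois).hits == ("hand",)

    def test_miss(self, make_scanpath, simple_aois):
        sp = make_scanpath([100], xs=[30], ys=[30])
        assert hit_test(sp, simple_aois).hits == (None,)

    def test_image_without_polygons(self, make_scanpath, simple_aois):
        sp = make_scanpath([100], xs=[5], ys=[5], ref_images=[2])
        assert hit_test(sp, simple_aois).hits == (None,)

    def test_overlap_smallest_area_wins(self, make_scanpath):
        aois = AOISet("moses", [square("big", 1, 0, 0, 100), square("small", 1, 40, 40, 10)])
        sp = make_scanpath([100, 100], xs=[45, 5], ys=[45, 5])
        assert hit_test(sp, aois).hits == ("small", "big")

    def test_overlap_equal_area_lexicographic(self, make_scanpath):
        aois = AOISet("moses", [square("zeta", 1, 0, 0, 10), square("alpha", 1, 5, 0, 10)])
        sp = make_scanpath([100], xs=[7], ys=[5])  # inside both
        assert hit_test(sp, aois).hits == ("alpha",)

    def test_wrong_sculpture_rejected(self, make_scanpath, simple_aois):
        with pytest.raises(ValidationError):
            hit_test(make_scanpath([100], sculpture="daphne"), simple_aois)

    def test_agrees_with_even_odd_oracle(self, make_scanpath, rng):
        # concave polygon (an L shape) plus a triangle
        lshape = ((10.0, 10.0), (60.0, 10.0), (60.0, 30.0), (30.0, 30.0),
                  (30.0, 60.0), (10.0, 60.0))
        triangle = ((70.0, 70.0), (95.0, 75.0), (80.0, 95.0))
        aois = AOISet("moses", [AOIRegion("ell", 1, lshape), AOIRegion("tri", 1, triangle)])
        xs = rng.uniform(0, 100, 1000)
        ys = rng.uniform(0, 100, 1000)
        sp = make_scanpath([100] * 1000, xs=xs, ys=ys)
        hits = hit_test(sp, aois).hits
        for x, y, hit in zip(xs, ys, hits):
            expected = (
                "ell" if even_odd_contains(x, y, lshape)
                else "tri" if even_odd_contains(x, y, triangle)
                else None
            )
            assert hit == expected, (x, y)


class TestCoverage:
    def test_feature_identity_across_images(self, make_scanpath):
        aois = AOISet("moses", [square("head", 1, 0, 0, 10), square("head", 5, 0, 0, 10)])
        sp = make_scanpath([100, 100], xs=[5, 5], ys=[5, 5], ref_images=[1, 5])
        hits = hit_test(sp, aois)
        assert n_features_fixated(hits) == 1

    def test_distinct_count(self):
        assert n_features_fixated(["head", "hands", "head"]) == 2
        assert n_features_fixated([None, None]) == 0

    @pytest.mark.parametrize(
        "hits,expected",
        [(["a", None, None, "b", "a"] + [None] * 5, 30.0),
         (["a", "a"], 100.0),
         ([None, None], 0.0)],
    )
    def test_pct_on_features(self, hits, expected):
        assert pct_on_features(hits) == pytest.approx(expected)

    def test_pct_empty_undefined(self):
        with pytest.warns(UserWarning):
            assert math.isnan(pct_on_features([]))

    def test_pct_invariant_under_reordering(self, rng):
        hits = list(rng.choice(["a", "b", None], size=30))
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert pct_on_features(hits) == pct_on_features(shuffled)


def oracle_revisits(hits):
    """Independent per-feature state machine: a revisit is a hit of a
    previously visited feature after >=1 fixation outside it."""
    count = 0
    for feature in {h for h in hits if h is not None}:
        visited = False
        outside_since = False
        for h in hits:
            if h == feature:
                if visited and outside_since:
                    count += 1
                visited = True
                outside_since = False
            elif visited:
                outside_since = True
    return count


class TestRevisits:
    @pytest.mark.parametrize(
        "hits,expected",
        [
            (["A", None, "A"], 1),      # the definition's own scenario
            (["A", "A", "A"], 0),       # dwelling is not a revisit
            (["A", "B", "A", "B"], 2),  # another feature counts as leaving
            ([], 0),
            ([None, None], 0),
            (["A", None, "A", None, "A"], 2),
        ],
    )
    def test_examples(self, hits, expected):
        assert revisit_count(hits) == expected

    def test_sorted_sequence_has_no_revisits(self):
        """Revisits are order-sensitive: grouping all hits of a feature
        together removes every revisit."""
        hits = ["A", "B", None, "A", "B", "A"]
        assert revisit_count(hits) > 0
        assert revisit_count(sorted(h for h in hits if h) + [None]) == 0

    def test_bounded_by_visits_minus_one(self, rng):
        for _ in range(50):
            hits = list(rng.choice(["A", "B", None], size=12))
            runs = visit_runs(hits)
            for feature in set(runs):
                per_feature = [h if h == feature else None for h in hits]
                assert revisit_count(per_feature) <= max(0, runs.count(feature) - 1)

    def test_exhaustive_enumeration_matches_oracle(self):
        """All hit sequences of length <= 6 over two features and a miss."""
        for length in range(7):
            for hits in product(["A", "B", None], repeat=length):
                assert revisit_count(hits) == oracle_revisits(hits), hits

    def test_per_minute_normalization(self):
        assert revisits_per_minute(["A", None, "A"], 30_000) == pytest.approx(2.0)

    def test_invalid_inspection_time(self):
        with pytest.raises(ValidationError):
            revisits_per_minute(["A"], 0)
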