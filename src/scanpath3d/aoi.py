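"""Basic-feature (AOI) metrics: coverage, hit percentage and revisits.

Basic features are expert-defined areas of interest on the sculpture —
physical features (a head, a hand, a leaf cluster) that keep one
identity across all eight reference images.  Each fixation is hit-tested
against the polygons of its own reference image; from the resulting hit
sequence the module computes, per participant and sculpture:

* the number of distinct features fixated (identity shared across
  perspectives),
* the percentage of fixations landing on any feature, and
* revisits per minute — a revisit is a re-entry of gaze into a feature
  after at least one fixation outside that feature following a prior
  visit; continuous dwelling inside a feature is never a revisit.

Point-in-polygon membership is boundary-inclusive.  A fixation inside
several overlapping polygons is assigned to the smallest-area polygon,
with lexicographic feature_id as the final tie-break.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from shapely.geometry import Point
from shapely.prepared import prep

from .errors import ValidationError
from .io import AOISet, ScanPath


@dataclass
class AOIHitSequence:
    """Per-fixation feature hits (feature_id or None) in scanpath order."""

    participant_id: str
    sculpture_id: str
    hits: tuple[str | None, ...]

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class AOIMetrics:
    participant_id: str
    sculpture_id: str
    n_features_fixated: int
    pct_on_features: float   # NaN for an empty scanpath
    revisits: int
    revisits_per_min: float


def hit_test(scanpath: ScanPath, aoi_set: AOISet) -> AOIHitSequence:
    """Assign each fixation to the basic feature containing it, if any.

    Containment is tested against the polygons defined on the
    fixation's own reference image and is boundary-inclusive.  A
    fixation on an image with no polygons hits nothing.
    """
    if scanpath.sculpture_id != aoi_set.sculpture_id:
        raise ValidationError(
            f"AOI set is for {aoi_set.sculpture_id!r}, scanpath is on "
            f"{scanpath.sculpture_id!r}"
        )
    # smallest-area-first, then feature_id, so the first containing
    # polygon wins the overlap tie-break
    by_image: dict[int, list[tuple[str, object]]] = {}
    for region in aoi_set.regions:
        poly = region.polygon
        by_image.setdefault(region.ref_image, []).append(
            (poly.area, region.feature_id, prep(poly))
        )
    for regions in by_image.values():
        regions.sort(key=lambda item: (item[0], item[1]))

    hits: list[str | None] = []
    for f in scanpath.fixations:
        hit = None
        point = Point(f.x, f.y)
        for _, feature_id, prepared in by_image.get(f.ref_image, ()):
            if prepared.covers(point):
                hit = feature_id
                break
        hits.append(hit)
    return AOIHitSequence(
        participant_id=scanpath.participant_id,
        sculpture_id=scanpath.sculpture_id,
        hits=tuple(hits),
    )


def _hits(hits: AOIHitSequence | Sequence[str | None]) -> Sequence[str | None]:
    return hits.hits if isinstance(hits, AOIHitSequence) else hits


def n_features_fixated(hits: AOIHitSequence | Sequence[str | None]) -> int:
    """Number of distinct basic features with at least one hit."""
    return len({h for h in _hits(hits) if h is not None})


def pct_on_features(hits: AOIHitSequence | Sequence[str | None]) -> float:
    """Percentage of fixations that land on any basic feature.

    NaN (with a warning) for an empty sequence.
    """
    seq = _hits(hits)
    if not seq:
        warnings.warn("empty scanpath: percentage on features undefined", stacklevel=2)
        return math.nan
    return 100.0 * sum(1 for h in seq if h is not None) / len(seq)


def visit_runs(hits: AOIHitSequence | Sequence[str | None]) -> list[str]:
    """Maximal runs of consecutive same-feature hits, in order.

    ``[A, A, None, B, A]`` -> ``[A, B, A]``.  Runs are the unit of
    visiting: consecutive fixations inside one feature are one visit.
    """
    runs: list[str] = []
    previous: str | None = None
    for h in _hits(hits):
        if h is not None and h != previous:
            runs.append(h)
        previous = h
    return runs


def revisit_count(hits: AOIHitSequence | Sequence[str | None]) -> int:
    """Total revisits across features.

    A revisit of a feature is a re-entry after at least one fixation
    outside it (a miss or a fixation on another feature) following a
    prior visit, i.e. every visit run of a feature beyond its first.
    Dwelling — consecutive fixations within one feature — counts once.
    """
    runs = visit_runs(hits)
    return sum(runs.count(f) - 1 for f in set(runs))


def revisits_per_minute(
    hits: AOIHitSequence | Sequence[str | None], inspection_time_ms: float
) -> float:
    """Revisits summed across features per minute of inspection time."""
    if inspection_time_ms <= 0:
        raise ValidationError(
            f"inspection_time_ms must be > 0, got {inspection_time_ms}"
        )
    return revisit_count(hits) / (inspection_time_ms / 60000.0)


def analyze_scanpath(scanpath: ScanPath, aoi_set: AOISet) -> AOIMetrics:
    """All AOI metrics for one participant on one sculpture."""
    hits = hit_test(scanpath, aoi_set)
    revisits = revisit_count(hits)
    time_ms = scanpath.inspection_time
    return AOIMetrics(
        participant_id=scanpath.participant_id,
        sculpture_id=scanpath.sculpture_id,
        n_features_fixated=n_features_fixated(hits),
        pct_on_features=pct_on_features(hits) if len(hits) else math.nan,
        revisits=revisits,
        revisits_per_min=(
            revisits / (time_ms / 60000.0) if time_ms > 0 else 0.0
        ),
    )
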