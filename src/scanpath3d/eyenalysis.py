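"""Scanpath distance by double mapping in (x, y, scaled duration) space.

Two scanpaths S and T are compared by mapping every fixation of S to
its nearest fixation in T and every fixation of T to its nearest in S
(the "double mapping"), summing the Euclidean distances of all mapped
pairs and dividing by the larger of the two fixation counts.  Each
fixation is a 3-D point: its reference-image position (x, y) in px and
its duration scaled into px by a per-sculpture conversion factor chosen
so that the longest fixation observed on the sculpture spans the
sculpture's pixel height.  Because fixations on a sculpture are spread
over eight reference images (viewing perspectives), the distance is
computed per reference image and averaged over the images on which
both participants fixated at least once.

The resulting participant-by-participant matrix is symmetric with a
zero diagonal; cells are grouped by expertise divergence for the group
summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .expertise import ExpertiseProfile
from .io import ScanPath


@dataclass(frozen=True)
class ConversionFactor:
    """Px-per-ms scale mapping fixation duration onto the third axis."""

    sculpture_id: str
    value: float
    source: str  # "computed" | "configured"

    def __post_init__(self):
        if self.value <= 0:
            raise ValidationError(f"conversion factor must be > 0, got {self.value}")


@dataclass
class SculptureDistanceDetail:
    """Per-pair distance with bookkeeping about skipped reference images."""

    value: float          # NaN when no reference image is shared
    n_images_used: int
    n_images_skipped: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass
class DistanceMatrix:
    """Symmetric participant-by-participant distance matrix for one sculpture."""

    sculpture_id: str
    participants: list[str]
    values: np.ndarray       # (n, n), zero diagonal, NaN for undefined cells
    divergence: np.ndarray   # (n, n) int expertise-level divergence

    def cell(self, a: str, b: str) -> float:
        i, j = self.participants.index(a), self.participants.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.participants, columns=self.participants
        )


def point_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two fixation points in (x, y, z_dur)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sqrt(np.sum((p - q) ** 2)))


def double_map_distance(S: np.ndarray, T: np.ndarray) -> float:
    """Double-mapped nearest-neighbour distance between two point sets.

    Every point of S is mapped to its nearest point of T and vice
    versa; the summed pair distances are normalized by
    ``max(|S|, |T|)`` so that unequal fixation counts do not inflate
    the measure.

    Nearest-neighbour search is exact (full pairwise enumeration); ties
    resolve to the lower ordinal, which leaves the distance unchanged
    but keeps mapping traces deterministic.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if S.shape[0] == 0 or T.shape[0] == 0:
        raise ValidationError("double_map_distance requires non-empty point sets")
    D = cdist(S, T)
    total = D.min(axis=1).sum() + D.min(axis=0).sum()
    return float(total / max(S.shape[0], T.shape[0]))


def compute_conversion_factor(
    scanpaths: Iterable[ScanPath], sculpture_height_px: float
) -> ConversionFactor:
    """Cohort-wide conversion factor for one sculpture.

    value = sculpture height (px) / longest fixation duration (ms)
    across all scanpaths on the sculpture, so the duration axis spans
    the same range as the y axis.
    """
    scanpaths = list(scanpaths)
    if sculpture_height_px <= 0:
        raise ValidationError(
            f"sculpture_height_px must be > 0, got {sculpture_height_px}"
        )
    sculpture_ids = {sp.sculpture_id for sp in scanpaths}
    if len(sculpture_ids) != 1:
        raise ValidationError(
            f"conversion factor is per sculpture; got {sorted(sculpture_ids)}"
        )
    durations = [f.duration for sp in scanpaths for f in sp.fixations]
    if not durations:
        raise ValidationError("cannot compute a conversion factor without fixations")
    return ConversionFactor(
        sculpture_id=sculpture_ids.pop(),
        value=sculpture_height_px / max(durations),
        source="computed",
    )


def to_points3(scanpath: ScanPath, factor: ConversionFactor) -> dict[int, np.ndarray]:
    """Convert a scanpath to 3-D points grouped by reference image.

    Fixation order (ordinal) is preserved within each image's array.
    """
    by_image: dict[int, list[list[float]]] = {}
    for f in scanpath.fixations:
        by_image.setdefault(f.ref_image, []).append(
            [f.x, f.y, f.duration * factor.value]
        )
    return {img: np.asarray(pts, dtype=float) for img, pts in sorted(by_image.items())}


def sculpture_distance_detail(
    a: ScanPath, b: ScanPath, factor: ConversionFactor
) -> SculptureDistanceDetail:
    """Distance between two participants' scanpaths on one sculpture.

    The double-mapping distance is computed for every reference image
    on which *both* scanpaths have at least one fixation, then
    averaged.  Images fixated by only one participant are skipped and
    counted; if no image is shared the distance is undefined (NaN, with
    a warning).
    """
    if a.sculpture_id != b.sculpture_id:
        raise ValidationError(
            f"scanpaths are on different sculptures: {a.sculpture_id!r} vs {b.sculpture_id!r}"
        )
    pa = to_points3(a, factor)
    pb = to_points3(b, factor)
    shared = sorted(set(pa) & set(pb))
    skipped = len(set(pa) | set(pb)) - len(shared)
    if not shared:
        warnings.warn(
            f"no shared reference image between {a.participant_id} and "
            f"{b.participant_id} on {a.sculpture_id}: distance undefined",
            stacklevel=2,
        )
        return SculptureDistanceDetail(math.nan, 0, skipped)
    per_image = [double_map_distance(pa[img], pb[img]) for img in shared]
    return SculptureDistanceDetail(float(np.mean(per_image)), len(shared), skipped)


def sculpture_distance(a: ScanPath, b: ScanPath, factor: ConversionFactor) -> float:
    """Mean per-reference-image double-mapping distance (px); NaN if undefined."""
    return sculpture_distance_detail(a, b, factor).value


def pairwise_matrix(
    scanpaths: Iterable[ScanPath],
    profiles: Mapping[str, ExpertiseProfile],
    factor: ConversionFactor,
) -> DistanceMatrix:
    """Full symmetric distance matrix over all participants on one sculpture."""
    scanpaths = sorted(scanpaths, key=lambda sp: sp.participant_id)
    if len(scanpaths) < 2:
        raise ValidationError("pairwise matrix needs at least 2 scanpaths")
    ids = [sp.participant_id for sp in scanpaths]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate participant in scanpath collection")
    for pid in ids:
        if pid not in profiles:
            raise ValidationError(f"no expertise profile for participant {pid}")
    n = len(ids)
    values = np.zeros((n, n))
    divergence = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        values[i, j] = values[j, i] = sculpture_distance(
            scanpaths[i], scanpaths[j], factor
        )
        d = abs(int(profiles[ids[i]].level) - int(profiles[ids[j]].level))
        divergence[i, j] = divergence[j, i] = d
    return DistanceMatrix(
        sculpture_id=scanpaths[0].sculpture_id,
        participants=ids,
        values=values,
        divergence=divergence,
    )


def divergence_summary(matrix: DistanceMatrix) -> pd.DataFrame:
    """Pool off-diagonal distances by expertise divergence: mean, SD, N.

    Self-comparisons (the zero diagonal) are excluded; undefined cells
    (NaN) are dropped with a warning.  SD is the sample standard
    deviation; a single-pair group gets SD 0 with a degenerate flag.
    """
    pooled: dict[int, list[float]] = {}
    n_missing = 0
    n = len(matrix.participants)
    for i, j in combinations(range(n), 2):
        value = matrix.values[i, j]
        if math.isnan(value):
            n_missing += 1
            continue
        pooled.setdefault(int(matrix.divergence[i, j]), []).append(float(value))
    if n_missing:
        warnings.warn(
            f"{n_missing} undefined pairwise distance(s) excluded from the "
            "divergence summary",
            stacklevel=2,
        )
    rows = []
    for d, vals in sorted(pooled.items()):
        degenerate = len(vals) < 2
        if degenerate:
            warnings.warn(f"divergence {d}: single pair, SD degenerate", stacklevel=2)
        rows.append(
            {
                "divergence": d,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": 0.0 if degenerate else float(np.std(vals, ddof=1)),
                "sd_degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows, columns=["divergence", "n", "mean", "sd", "sd_degenerate"])
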