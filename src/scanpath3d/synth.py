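"""Synthetic fixation cohorts with the structure the analysis assumes.

The generator emulates the study design the package analyses: four
expertise groups of five participants each, two sculptures, eight
reference images (viewing perspectives) per sculpture.  Per participant
and sculpture it draws

* a fixation count from a Poisson distribution,
* a global/local *mode* sequence from a two-state Markov chain — with
  probability ``switch_persistence`` the current mode is kept,
  otherwise the mode is resampled as local with probability
  ``p_local`` (so the stationary local share is exactly ``p_local``
  and persistence 1.0 freezes the mode),
* fixation durations from the current mode's lognormal distribution
  (right-skewed, the standard model for fixation durations),
* a reference image uniformly over 1-8,
* a position either attracted into a basic-feature polygon (with
  probability ``aoi_attraction``, preferring previously visited
  features with probability ``revisit_bias``) or scattered with
  Gaussian jitter around the group's gaze centre — per-level centre
  offsets create the between-group scanpath separation that the
  divergence analysis should detect,
* cumulative onsets (duration plus an exponential inter-fixation gap),

and a years-of-experience value inside the level's band, so the
expertise classifier recovers the intended level.

Randomness comes from numpy Generators keyed by (seed, participant
index, sculpture index), so adding participants or sculptures does not
perturb existing participants' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import lognorm

from .errors import ConfigError
from .expertise import ExpertiseLevel, ExpertiseProfile, build_profiles
from .io import (
    AOIRegion,
    AOISet,
    N_REF_IMAGES,
    ScanPath,
    scanpaths_from_frame,
)

#: Years-of-experience band sampled per level (matching the published
#: observed ranges: laypersons 0, novices 0.25-4.5, semi-experts 6-9,
#: experts 14-29).
EXPERIENCE_BANDS: dict[ExpertiseLevel, tuple[float, float]] = {
    ExpertiseLevel.LAYPERSON: (0.0, 0.0),
    ExpertiseLevel.NOVICE: (0.25, 4.5),
    ExpertiseLevel.SEMI_EXPERT: (6.0, 9.0),
    ExpertiseLevel.EXPERT: (14.0, 29.0),
}


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one expertise group.

    p_local
        Stationary probability that a fixation is in local mode.
    dur_global, dur_local
        Lognormal (median ms, sigma) of the two modes' durations.
    switch_persistence
        Probability of keeping the current mode at each step.
    aoi_attraction
        Probability that a fixation is drawn inside a basic feature.
    n_fix
        Mean fixations per sculpture (Poisson).
    revisit_bias
        Probability an AOI-attracted fixation returns to an already
        visited feature rather than a random one.
    spatial_jitter_px
        Gaussian spread of non-AOI fixations around the gaze centre.
    gaze_center_offset
        (dx, dy) px offset of the group's gaze centre from the image
        centre; controls between-group scanpath separation.
    """

    p_local: float = 0.33
    dur_global: tuple[float, float] = (100.0, 0.30)
    dur_local: tuple[float, float] = (400.0, 0.35)
    switch_persistence: float = 0.75
    aoi_attraction: float = 0.05
    n_fix: float = 120.0
    revisit_bias: float = 0.3
    spatial_jitter_px: float = 70.0
    gaze_center_offset: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        for name in ("p_local", "switch_persistence", "aoi_attraction", "revisit_bias"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for name, (median, sigma) in (
            ("dur_global", self.dur_global),
            ("dur_local", self.dur_local),
        ):
            if median <= 0 or sigma <= 0:
                raise ConfigError(f"{name} needs positive (median, sigma), got {median, sigma}")
        if self.n_fix <= 0:
            raise ConfigError(f"n_fix must be > 0, got {self.n_fix}")
        if self.spatial_jitter_px <= 0:
            raise ConfigError(f"spatial_jitter_px must be > 0, got {self.spatial_jitter_px}")


@dataclass(frozen=True)
class GroupSpec:
    level: ExpertiseLevel
    n_participants: int
    params: GroupParams


@dataclass(frozen=True)
class SculptureConfig:
    sculpture_id: str
    image_width: float
    image_height: float
    sculpture_height_px: float
    n_features: int = 10

    def validate(self) -> None:
        if min(self.image_width, self.image_height, self.sculpture_height_px) <= 0:
            raise ConfigError(f"{self.sculpture_id}: image dimensions must be > 0")
        if self.n_features < 1:
            raise ConfigError(f"{self.sculpture_id}: n_features must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    sculptures: tuple[SculptureConfig, ...]
    seed: int = 0
    inter_fixation_gap_ms: float = 50.0

    def validate(self) -> None:
        if not self.groups or not self.sculptures:
            raise ConfigError("config needs at least one group and one sculpture")
        if self.inter_fixation_gap_ms < 0:
            raise ConfigError("inter_fixation_gap_ms must be >= 0")
        for spec in self.groups:
            if spec.n_participants < 1:
                raise ConfigError("each group needs >= 1 participant")
            spec.params.validate()
        for sc in self.sculptures:
            sc.validate()


@dataclass
class Cohort:
    """Generated fixation table, metadata and AOI sets."""

    fixations: pd.DataFrame
    meta: dict[str, float]
    aoi_sets: dict[str, AOISet]
    config: CohortConfig

    def scanpaths(self, sculpture_id: str | None = None) -> list[ScanPath]:
        frame = self.fixations
        if sculpture_id is not None:
            frame = frame[frame["sculpture_id"] == sculpture_id]
        return scanpaths_from_frame(frame, source="<synthetic>")

    def profiles(self, **thresholds) -> dict[str, ExpertiseProfile]:
        return build_profiles(self.meta, **thresholds)


def default_config(
    seed: int = 0,
    *,
    n_per_group: int = 5,
    n_fix: float = 120.0,
    offset_step_px: float = 60.0,
) -> CohortConfig:
    """Study-shaped default: 4 levels x n participants, 2 sculptures.

    Per-level gaze centres are offset by ``offset_step_px`` per level so
    scanpath distance grows with expertise divergence.
    """
    base = GroupParams(n_fix=n_fix)
    groups = tuple(
        GroupSpec(
            level=level,
            n_participants=n_per_group,
            params=replace(
                base, gaze_center_offset=(offset_step_px * int(level), 0.0)
            ),
        )
        for level in ExpertiseLevel
    )
    sculptures = (
        SculptureConfig("moses", image_width=600, image_height=800,
                        sculpture_height_px=600, n_features=10),
        SculptureConfig("daphne", image_width=500, image_height=1200,
                        sculpture_height_px=1050, n_features=14),
    )
    return CohortConfig(groups=groups, sculptures=sculptures, seed=seed)


# ---------------------------------------------------------------------------
# AOI layout
# ---------------------------------------------------------------------------

def _aoi_layout(config: CohortConfig, s_idx: int, sculpture: SculptureConfig) -> AOISet:
    """Axis-aligned rectangular basic features, one identity across images.

    Each feature has a base position; on every reference image the
    rectangle is shifted slightly (the feature seen from a different
    perspective), clipped to the image.
    """
    rng = np.random.default_rng([config.seed, 7, s_idx])
    w, h = sculpture.image_width, sculpture.image_height
    rect_w, rect_h = 0.06 * w, 0.06 * h
    regions = []
    for k in range(sculpture.n_features):
        feature_id = f"feature_{k + 1:02d}"
        base_cx = rng.uniform(0.2 * w, 0.8 * w)
        base_cy = rng.uniform(0.2 * h, 0.8 * h)
        for img in range(1, N_REF_IMAGES + 1):
            cx = float(np.clip(base_cx + rng.uniform(-0.04, 0.04) * w,
                               rect_w / 2, w - rect_w / 2))
            cy = float(np.clip(base_cy + rng.uniform(-0.04, 0.04) * h,
                               rect_h / 2, h - rect_h / 2))
            x0, x1 = cx - rect_w / 2, cx + rect_w / 2
            y0, y1 = cy - rect_h / 2, cy + rect_h / 2
            regions.append(
                AOIRegion(
                    feature_id=feature_id,
                    ref_image=img,
                    vertices=((x0, y0), (x1, y0), (x1, y1), (x0, y1)),
                )
            )
    return AOISet(sculpture_id=sculpture.sculpture_id, regions=regions)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sample_participant(
    rng: np.random.Generator,
    params: GroupParams,
    sculpture: SculptureConfig,
    aoi_set: AOISet,
    gap_ms: float,
) -> list[dict]:
    n = max(2, int(rng.poisson(params.n_fix)))
    center_x = sculpture.image_width / 2 + params.gaze_center_offset[0]
    center_y = sculpture.image_height / 2 + params.gaze_center_offset[1]
    regions_by_image: dict[int, list[AOIRegion]] = {}
    for region in aoi_set.regions:
        regions_by_image.setdefault(region.ref_image, []).append(region)

    rows = []
    mode_local = bool(rng.random() < params.p_local)
    onset = 0.0
    visited: list[str] = []
    for i in range(n):
        if i > 0:
            if rng.random() >= params.switch_persistence:
                mode_local = bool(rng.random() < params.p_local)
        median, sigma = params.dur_local if mode_local else params.dur_global
        duration = float(rng.lognormal(mean=math.log(median), sigma=sigma))
        ref_image = int(rng.integers(1, N_REF_IMAGES + 1))

        candidates = regions_by_image.get(ref_image, [])
        if candidates and rng.random() < params.aoi_attraction:
            revisitable = [r for r in candidates if r.feature_id in visited]
            if revisitable and rng.random() < params.revisit_bias:
                region = revisitable[int(rng.integers(len(revisitable)))]
            else:
                region = candidates[int(rng.integers(len(candidates)))]
            xs = [v[0] for v in region.vertices]
            ys = [v[1] for v in region.vertices]
            x = float(rng.uniform(min(xs), max(xs)))
            y = float(rng.uniform(min(ys), max(ys)))
            if region.feature_id not in visited:
                visited.append(region.feature_id)
        else:
            x = float(np.clip(rng.normal(center_x, params.spatial_jitter_px),
                              0, sculpture.image_width))
            y = float(np.clip(rng.normal(center_y, params.spatial_jitter_px),
                              0, sculpture.image_height))
        rows.append(
            {
                "ref_image": ref_image,
                "x": round(x, 2),
                "y": round(y, 2),
                "onset_ms": round(onset, 2),
                "duration_ms": round(duration, 2),
            }
        )
        onset += duration + float(rng.exponential(gap_ms)) if gap_ms > 0 else duration
    return rows


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort: fixation table, metadata, AOI sets.

    Deterministic given ``config.seed``; participant substreams are
    keyed by participant and sculpture index.
    """
    config.validate()
    aoi_sets = {
        sc.sculpture_id: _aoi_layout(config, s_idx, sc)
        for s_idx, sc in enumerate(config.sculptures)
    }
    records = []
    meta: dict[str, float] = {}
    p_idx = 0
    for spec in config.groups:
        lo, hi = EXPERIENCE_BANDS[spec.level]
        for _ in range(spec.n_participants):
            pid = f"p{p_idx + 1:02d}"
            rng_meta = np.random.default_rng([config.seed, 3, p_idx])
            meta[pid] = round(float(rng_meta.uniform(lo, hi)), 2) if hi > lo else lo
            for s_idx, sculpture in enumerate(config.sculptures):
                rng = np.random.default_rng([config.seed, 11, p_idx, s_idx])
                rows = _sample_participant(
                    rng,
                    spec.params,
                    sculpture,
                    aoi_sets[sculpture.sculpture_id],
                    config.inter_fixation_gap_ms,
                )
                for ordinal, row in enumerate(rows):
                    records.append(
                        {
                            "participant_id": pid,
                            "sculpture_id": sculpture.sculpture_id,
                            **row,
                            "ordinal": ordinal,
                        }
                    )
            p_idx += 1
    frame = pd.DataFrame.from_records(
        records,
        columns=[
            "participant_id",
            "sculpture_id",
            "ref_image",
            "x",
            "y",
            "onset_ms",
            "duration_ms",
            "ordinal",
        ],
    )
    return Cohort(fixations=frame, meta=meta, aoi_sets=aoi_sets, config=config)


# ---------------------------------------------------------------------------
# Closed-form expectations (parameter-recovery targets)
# ---------------------------------------------------------------------------

def _local_label_prob(median: float, sigma: float, threshold_ms: float) -> float:
    """P(lognormal(median, sigma) duration > threshold)."""
    return float(lognorm.sf(threshold_ms, s=sigma, scale=median))


def expected_metrics(
    config: CohortConfig, threshold_ms: float = 187.0
) -> dict[ExpertiseLevel, dict[str, float]]:
    """Analytic per-group expectations of the global/local metrics.

    The expected global/local ratio is (1 - P(local label)) /
    P(local label), where the local-label probability accounts for
    *threshold leakage*: global-mode durations that exceed the
    threshold and local-mode durations that fall below it.  The
    expected switch rate combines the chain's mode-transition
    probabilities with the per-mode label probabilities and the mean
    fixation tempo (mean duration plus inter-fixation gap).
    """
    config.validate()
    out: dict[ExpertiseLevel, dict[str, float]] = {}
    for spec in config.groups:
        g = spec.params
        p = g.p_local
        s = g.switch_persistence
        a = _local_label_prob(*g.dur_local, threshold_ms)   # local label | local mode
        b = _local_label_prob(*g.dur_global, threshold_ms)  # local label | global mode
        p_label_local = p * a + (1 - p) * b
        gl_ratio = (
            math.inf if p_label_local == 0 else (1 - p_label_local) / p_label_local
        )
        # transition matrix of the mode chain (stay s, else resample)
        t_ll = s + (1 - s) * p
        t_lg = (1 - s) * (1 - p)
        t_gl = (1 - s) * p
        t_gg = s + (1 - s) * (1 - p)

        def diff(q1: float, q2: float) -> float:
            return q1 * (1 - q2) + (1 - q1) * q2

        p_switch = p * (t_ll * diff(a, a) + t_lg * diff(a, b)) + (1 - p) * (
            t_gl * diff(b, a) + t_gg * diff(b, b)
        )
        mean_dur = p * g.dur_local[0] * math.exp(g.dur_local[1] ** 2 / 2) + (
            1 - p
        ) * g.dur_global[0] * math.exp(g.dur_global[1] ** 2 / 2)
        n = g.n_fix
        span_ms = n * mean_dur + (n - 1) * config.inter_fixation_gap_ms
        switch_rate_hz = (n - 1) * p_switch / (span_ms / 1000.0)
        out[spec.level] = {
            "gl_ratio": gl_ratio,
            "switch_rate_hz": switch_rate_hz,
            "p_label_local": p_label_local,
            "mean_duration_ms": mean_dur,
        }
    return out
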