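"""Expertise classification and pairwise divergence grouping.

Participants are assigned one of four expertise levels from their years
of sculpting experience: no experience at all is a layperson, under
five years a novice, five to ten years a semi-expert, and more than ten
years an expert.  The published thresholds leave exactly 5 and exactly
10 years unassigned; this implementation includes both boundaries in
the semi-expert band (configurable via ``novice_max`` /
``semi_expert_max``).

For pairwise scanpath comparisons, every unordered pair of distinct
participants is assigned a *divergence*: the absolute difference of the
two expertise levels (0-3).  With four groups of g participants each
this yields 4*g*(g-1)/2 pairs at divergence 0 and (4-d)*g**2 pairs at
divergence d in {1, 2, 3} — for g = 5: 40, 75, 50 and 25 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from itertools import combinations
from statistics import mean
from typing import Iterable, Mapping

from .errors import ValidationError


class ExpertiseLevel(IntEnum):
    LAYPERSON = 0
    NOVICE = 1
    SEMI_EXPERT = 2
    EXPERT = 3

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    ExpertiseLevel.LAYPERSON: "layperson",
    ExpertiseLevel.NOVICE: "novice",
    ExpertiseLevel.SEMI_EXPERT: "semi_expert",
    ExpertiseLevel.EXPERT: "expert",
}


@dataclass(frozen=True)
class ExpertiseProfile:
    participant_id: str
    years_experience: float
    level: ExpertiseLevel


@dataclass
class DivergenceGroup:
    """All participant pairs sharing one expertise-level divergence."""

    divergence: int
    pairs: list[tuple[str, str]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def classify_expertise(
    years_experience: float,
    *,
    novice_max: float = 5.0,
    semi_expert_max: float = 10.0,
) -> ExpertiseLevel:
    """Map years of sculpting experience to an expertise level.

    0 years -> layperson; (0, novice_max) -> novice;
    [novice_max, semi_expert_max] -> semi-expert; above -> expert.
    """
    if years_experience < 0:
        raise ValidationError(f"years_experience must be >= 0, got {years_experience}")
    if years_experience == 0:
        return ExpertiseLevel.LAYPERSON
    if years_experience < novice_max:
        return ExpertiseLevel.NOVICE
    if years_experience <= semi_expert_max:
        return ExpertiseLevel.SEMI_EXPERT
    return ExpertiseLevel.EXPERT


def build_profiles(
    meta: Mapping[str, float],
    *,
    novice_max: float = 5.0,
    semi_expert_max: float = 10.0,
) -> dict[str, ExpertiseProfile]:
    """Classify a {participant_id: years} mapping into profiles."""
    return {
        pid: ExpertiseProfile(
            participant_id=pid,
            years_experience=years,
            level=classify_expertise(
                years, novice_max=novice_max, semi_expert_max=semi_expert_max
            ),
        )
        for pid, years in meta.items()
    }


def divergence_groups(
    profiles: Mapping[str, ExpertiseProfile] | Iterable[ExpertiseProfile],
) -> dict[int, DivergenceGroup]:
    """Partition all unordered participant pairs by expertise divergence.

    Every pair of distinct participants lands in exactly one group, so
    the group sizes sum to C(n, 2).
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    else:
        profiles = list(profiles)
    if len(profiles) < 2:
        raise ValidationError("divergence grouping needs at least 2 profiles")
    groups: dict[int, DivergenceGroup] = {}
    ordered = sorted(profiles, key=lambda p: p.participant_id)
    for a, b in combinations(ordered, 2):
        d = abs(int(a.level) - int(b.level))
        groups.setdefault(d, DivergenceGroup(divergence=d, pairs=[])).pairs.append(
            (a.participant_id, b.participant_id)
        )
    return dict(sorted(groups.items()))


def mean_experience_by_level(
    profiles: Mapping[str, ExpertiseProfile] | Iterable[ExpertiseProfile],
) -> dict[ExpertiseLevel, float]:
    """Mean years of experience per expertise level (metadata summary)."""
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    by_level: dict[ExpertiseLevel, list[float]] = {}
    for p in profiles:
        by_level.setdefault(p.level, []).append(p.years_experience)
    return {level: mean(years) for level, years in sorted(by_level.items())}
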