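"""Global/local fixation labelling, ratio and switching frequency.

Short fixations mark a *global* (ambient) viewing mode — broad
exploration of the whole sculpture — while long fixations mark a
*local* (focal) mode of detailed inspection.  The two are separated by
a duration threshold, by default 187 ms; a fixation is local iff its
duration is strictly greater than the threshold.  The threshold can
also be recomputed as the cohort's mean fixation duration
(``threshold="cohort_mean"``).

Per participant and sculpture this module reports the global/local
count ratio and the switching frequency: the number of transitions
between the two labels in consecutive fixations, divided by the
inspection time in seconds (Hz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expertise import ExpertiseLevel, ExpertiseProfile
from .io import ScanPath

GLOBAL = "global"
LOCAL = "local"

#: Default duration threshold separating global from local fixations, ms.
DEFAULT_THRESHOLD_MS = 187.0


@dataclass
class GlobalLocalResult:
    participant_id: str
    sculpture_id: str
    n_global: int
    n_local: int
    gl_ratio: float          # NaN when undefined (no local fixations)
    ratio_defined: bool
    switch_rate: float       # Hz


def _durations(scanpath: ScanPath | Sequence[float]) -> list[float]:
    if isinstance(scanpath, ScanPath):
        return scanpath.durations()
    return list(scanpath)


def label_fixations(
    scanpath: ScanPath | Sequence[float],
    threshold_ms: float = DEFAULT_THRESHOLD_MS,
) -> list[str]:
    """Label each fixation ``"local"`` iff duration > threshold, else ``"global"``.

    Accepts a :class:`~scanpath3d.io.ScanPath` or a bare duration
    sequence; order is preserved.  A duration exactly at the threshold
    is global (the local rule is a strict inequality).
    """
    if threshold_ms <= 0:
        raise ValidationError(f"threshold_ms must be > 0, got {threshold_ms}")
    return [LOCAL if d > threshold_ms else GLOBAL for d in _durations(scanpath)]


def global_local_ratio(labels: Sequence[str]) -> float:
    """Count of global fixations divided by count of local fixations.

    Returns NaN (with a warning) when there is no local fixation; the
    participant is then excluded from group means rather than silently
    dropped.
    """
    n_global = sum(1 for lab in labels if lab == GLOBAL)
    n_local = len(labels) - n_global
    if n_local == 0:
        warnings.warn(
            "global/local ratio undefined: no local fixations", stacklevel=2
        )
        return math.nan
    return n_global / n_local


def switch_count(labels: Sequence[str]) -> int:
    """Number of label changes between consecutive fixations."""
    return sum(1 for a, b in zip(labels, labels[1:]) if a != b)


def switch_rate(labels: Sequence[str], inspection_time_ms: float) -> float:
    """Switches between global and local viewing per second of inspection."""
    if inspection_time_ms <= 0:
        raise ValidationError(
            f"inspection_time_ms must be > 0, got {inspection_time_ms}"
        )
    return switch_count(labels) / (inspection_time_ms / 1000.0)


def cohort_mean_duration(scanpaths: Iterable[ScanPath]) -> float:
    """Mean fixation duration over every fixation in the cohort, ms."""
    durations = [f.duration for sp in scanpaths for f in sp.fixations]
    if not durations:
        raise ValidationError("cannot compute a mean duration without fixations")
    return float(np.mean(durations))


def resolve_threshold(
    threshold: float | str, scanpaths: Iterable[ScanPath]
) -> float:
    """Resolve a numeric threshold or the ``"cohort_mean"`` mode."""
    if isinstance(threshold, str):
        if threshold != "cohort_mean":
            raise ValidationError(f"unknown threshold mode: {threshold!r}")
        return cohort_mean_duration(scanpaths)
    return float(threshold)


def analyze_scanpath(
    scanpath: ScanPath,
    threshold_ms: float = DEFAULT_THRESHOLD_MS,
    *,
    inspection: str = "span",
) -> GlobalLocalResult:
    """Global/local metrics for one participant on one sculpture.

    ``inspection`` selects the time base for the switch rate: ``"span"``
    (end of last fixation minus onset of first; default) or ``"sum"``
    (total fixation time).
    """
    labels = label_fixations(scanpath, threshold_ms)
    n_local = sum(1 for lab in labels if lab == LOCAL)
    n_global = len(labels) - n_local
    if inspection == "span":
        time_ms = scanpath.inspection_time
    elif inspection == "sum":
        time_ms = scanpath.total_fixation_time
    else:
        raise ValidationError(f"unknown inspection mode: {inspection!r}")
    rate = switch_rate(labels, time_ms) if time_ms > 0 else 0.0
    if n_local == 0:
        ratio, defined = math.nan, False
        warnings.warn(
            f"participant {scanpath.participant_id}: no local fixations, "
            "global/local ratio undefined",
            stacklevel=2,
        )
    else:
        ratio, defined = n_global / n_local, True
    return GlobalLocalResult(
        participant_id=scanpath.participant_id,
        sculpture_id=scanpath.sculpture_id,
        n_global=n_global,
        n_local=n_local,
        gl_ratio=ratio,
        ratio_defined=defined,
        switch_rate=rate,
    )


def group_summary(
    values: Mapping[str, float],
    profiles: Mapping[str, ExpertiseProfile],
    *,
    metric: str = "value",
) -> pd.DataFrame:
    """Per-expertise-level mean and SD of a per-participant metric.

    Returns one row per non-empty level plus a ``total`` row (the mean
    over all included participants).  NaN values are excluded with a
    warning; a single-participant level gets SD 0 and a degenerate
    flag.  SD is the sample standard deviation (n-1 denominator).
    """
    included: dict[ExpertiseLevel, list[float]] = {}
    all_values: list[float] = []
    for pid, value in values.items():
        if pid not in profiles:
            raise ValidationError(f"no expertise profile for participant {pid}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            warnings.warn(
                f"participant {pid}: undefined metric excluded from group summary",
                stacklevel=2,
            )
            continue
        included.setdefault(profiles[pid].level, []).append(float(value))
        all_values.append(float(value))
    for level in ExpertiseLevel:
        if any(p.level == level for p in profiles.values()) and level not in included:
            warnings.warn(f"level {level.label}: no included participants", stacklevel=2)

    def _row(group: str, vals: list[float]) -> dict:
        degenerate = len(vals) < 2
        return {
            "group": group,
            "metric": metric,
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "sd": 0.0 if degenerate else float(np.std(vals, ddof=1)),
            "sd_degenerate": degenerate,
        }

    rows = [_row(level.label, vals) for level, vals in sorted(included.items())]
    if all_values:
        rows.append(_row("total", all_values))
    return pd.DataFrame(
        rows, columns=["group", "metric", "n", "mean", "sd", "sd_degenerate"]
    )
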