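"""End-to-end orchestration: inputs -> full result-table bundle.

``run_all`` reads a fixation table, participant metadata and AOI
definitions, then writes per-participant global/local metrics,
switching rates, per-sculpture distance matrices, the divergence
summary, AOI metrics and a run manifest (config hash, package version,
warning counts, the design toggles in effect).  Any stage failure
removes partial outputs and re-raises with the stage named.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from . import aoi as aoi_mod
from . import eyenalysis, globallocal
from .errors import ValidationError
from .expertise import build_profiles, divergence_groups
from .io import (
    AOISet,
    read_aoi_set,
    read_fixation_table,
    read_metadata,
    write_summary_table,
)


@dataclass
class RunConfig:
    fixations_path: str
    metadata_path: str
    aoi_paths: dict[str, str] = field(default_factory=dict)  # sculpture_id -> path
    out_dir: str = "results"
    threshold_ms: float | str = globallocal.DEFAULT_THRESHOLD_MS
    heights_px: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)  # overrides heights
    novice_max: float = 5.0
    semi_expert_max: float = 10.0
    inspection: str = "span"

    def to_dict(self) -> dict:
        return {
            "fixations_path": str(self.fixations_path),
            "metadata_path": str(self.metadata_path),
            "aoi_paths": {k: str(v) for k, v in self.aoi_paths.items()},
            "out_dir": str(self.out_dir),
            "threshold_ms": self.threshold_ms,
            "heights_px": dict(self.heights_px),
            "factors": dict(self.factors),
            "novice_max": self.novice_max,
            "semi_expert_max": self.semi_expert_max,
            "inspection": self.inspection,
        }


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage; return the manifest dict.

    Output files (CSV) under ``config.out_dir``::

        globallocal.csv         per-participant ratio metrics + level summary
        switching.csv           per-participant switch rates + level summary
        distances_<sculpt>.csv  long-format pairwise distance matrix
        divergence_summary.csv  pooled distances by expertise divergence
        aoi_metrics.csv         per-participant AOI metrics + level summaries
        manifest.json           config hash, versions, warning counts
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    caught: list[warnings.WarningMessage] = []
    stage = "setup"

    def _write(name: str, rows, **kwargs) -> None:
        path = out_dir / name
        write_summary_table(rows, path, **kwargs)
        written.append(path)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "read inputs"
            scanpaths = read_fixation_table(config.fixations_path)
            meta = read_metadata(config.metadata_path)
            profiles = build_profiles(
                meta,
                novice_max=config.novice_max,
                semi_expert_max=config.semi_expert_max,
            )
            aoi_sets: dict[str, AOISet] = {
                sid: read_aoi_set(path) for sid, path in config.aoi_paths.items()
            }
            sculptures = sorted({sp.sculpture_id for sp in scanpaths})

            stage = "global/local analysis"
            threshold = globallocal.resolve_threshold(config.threshold_ms, scanpaths)
            gl_rows, sw_rows = [], []
            ratios: dict[str, dict[str, float]] = {s: {} for s in sculptures}
            rates: dict[str, dict[str, float]] = {s: {} for s in sculptures}
            for sp in scanpaths:
                res = globallocal.analyze_scanpath(
                    sp, threshold, inspection=config.inspection
                )
                ratios[sp.sculpture_id][sp.participant_id] = res.gl_ratio
                rates[sp.sculpture_id][sp.participant_id] = res.switch_rate
                gl_rows.append(
                    {
                        "participant_id": res.participant_id,
                        "sculpture_id": res.sculpture_id,
                        "n_global": res.n_global,
                        "n_local": res.n_local,
                        "gl_ratio": res.gl_ratio if res.ratio_defined else "",
                    }
                )
                sw_rows.append(
                    {
                        "participant_id": res.participant_id,
                        "sculpture_id": res.sculpture_id,
                        "switch_rate_hz": res.switch_rate,
                    }
                )
            for sid in sculptures:
                for summary, rows in (
                    (globallocal.group_summary(ratios[sid], profiles, metric="gl_ratio"), gl_rows),
                    (globallocal.group_summary(rates[sid], profiles, metric="switch_rate_hz"), sw_rows),
                ):
                    for rec in summary.to_dict("records"):
                        rows.append(
                            {
                                "participant_id": f"<{rec['group']}>",
                                "sculpture_id": sid,
                                "n_global": "",
                                "n_local": "",
                                "gl_ratio": rec["mean"],
                                "switch_rate_hz": rec["mean"],
                                "sd": rec["sd"],
                            }
                        )
            _write(
                "globallocal.csv",
                gl_rows,
                columns=["participant_id", "sculpture_id", "n_global", "n_local", "gl_ratio", "sd"],
                formats={"gl_ratio": "ratio", "sd": "ratio"},
            )
            _write(
                "switching.csv",
                sw_rows,
                columns=["participant_id", "sculpture_id", "switch_rate_hz", "sd"],
                formats={"switch_rate_hz": "ratio", "sd": "ratio"},
            )

            stage = "scanpath distances"
            summary_rows = []
            for sid in sculptures:
                group = [sp for sp in scanpaths if sp.sculpture_id == sid]
                if len(group) < 2:
                    warnings.warn(f"{sid}: fewer than 2 scanpaths, distances skipped")
                    continue
                if sid in config.factors:
                    factor = eyenalysis.ConversionFactor(
                        sculpture_id=sid, value=config.factors[sid], source="configured"
                    )
                elif sid in config.heights_px:
                    factor = eyenalysis.compute_conversion_factor(
                        group, config.heights_px[sid]
                    )
                else:
                    raise ValidationError(
                        f"no conversion factor or sculpture height configured for {sid!r}"
                    )
                matrix = eyenalysis.pairwise_matrix(group, profiles, factor)
                cells = [
                    {
                        "participant_a": matrix.participants[i],
                        "participant_b": matrix.participants[j],
                        "divergence": int(matrix.divergence[i, j]),
                        "distance_px": matrix.values[i, j],
                    }
                    for i in range(len(matrix.participants))
                    for j in range(i + 1, len(matrix.participants))
                ]
                _write(
                    f"distances_{sid}.csv",
                    cells,
                    columns=["participant_a", "participant_b", "divergence", "distance_px"],
                    formats={"distance_px": "distance"},
                )
                for rec in eyenalysis.divergence_summary(matrix).to_dict("records"):
                    summary_rows.append(
                        {
                            "sculpture_id": sid,
                            "divergence": rec["divergence"],
                            "n": rec["n"],
                            "mean_px": rec["mean"],
                            "sd_px": rec["sd"],
                            "conversion_factor": factor.value,
                            "factor_source": factor.source,
                        }
                    )
            _write(
                "divergence_summary.csv",
                summary_rows,
                columns=[
                    "sculpture_id", "divergence", "n", "mean_px", "sd_px",
                    "conversion_factor", "factor_source",
                ],
                formats={"mean_px": "distance", "sd_px": "distance"},
            )

            stage = "AOI metrics"
            aoi_rows = []
            for sp in scanpaths:
                if sp.sculpture_id not in aoi_sets:
                    continue
                m = aoi_mod.analyze_scanpath(sp, aoi_sets[sp.sculpture_id])
                aoi_rows.append(
                    {
                        "participant_id": m.participant_id,
                        "sculpture_id": m.sculpture_id,
                        "n_features_fixated": m.n_features_fixated,
                        "pct_on_features": m.pct_on_features,
                        "revisits": m.revisits,
                        "revisits_per_min": m.revisits_per_min,
                    }
                )
            _write(
                "aoi_metrics.csv",
                aoi_rows,
                columns=[
                    "participant_id", "sculpture_id", "n_features_fixated",
                    "pct_on_features", "revisits", "revisits_per_min",
                ],
                formats={"pct_on_features": "ratio", "revisits_per_min": "ratio"},
            )

            stage = "manifest"
            n_pairs = {
                str(d): g.n_pairs for d, g in divergence_groups(profiles).items()
            }
            manifest = {
                "package_version": __version__,
                "config": config.to_dict(),
                "config_hash": _config_hash(config),
                "threshold_ms_resolved": threshold,
                "n_participants": len(profiles),
                "n_scanpaths": len(scanpaths),
                "n_pairs_by_divergence": n_pairs,
                "warnings": {
                    "count": len(caught),
                    "messages": sorted({str(w.message) for w in caught}),
                },
                "design_toggles": {
                    "threshold_boundary": "exactly-threshold durations are global",
                    "inspection_time": config.inspection,
                    "skipped_ref_images": "excluded from per-image mean",
                    "aoi_boundary": "inclusive",
                    "rounding": "half-up at printed precision",
                },
                "outputs": [p.name for p in written] + ["manifest.json"],
            }
            manifest_path = out_dir / "manifest.json"
            with open(manifest_path, "w") as handle:
                json.dump(manifest, handle, indent=2)
            written.append(manifest_path)
            return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
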