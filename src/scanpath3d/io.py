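"""Read and write fixation tables, AOI definitions, metadata and result tables.

All data-model invariants are enforced here, at the boundary: every
:class:`ScanPath` handed to the analysis modules is already validated
(positive durations, reference images 1-8, non-decreasing onsets,
consecutive ordinals), and every AOI polygon is simple with at least
three vertices.  Downstream code assumes, and never re-checks, these
invariants.

Coordinate convention: pixel coordinates with the origin at the top-left
of each reference image and y increasing downward (the usual
eye-tracking screen convention).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from shapely.geometry import Polygon

from .errors import SchemaError, ValidationError

#: Canonical fixation-table columns (``ordinal`` is optional on input).
FIXATION_COLUMNS = (
    "participant_id",
    "sculpture_id",
    "ref_image",
    "x",
    "y",
    "onset_ms",
    "duration_ms",
)

#: Number of viewing perspectives (reference images) per sculpture,
#: taken at 45 degree steps walking around the sculpture.
N_REF_IMAGES = 8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixation:
    """One gaze fixation mapped onto a reference image.

    Attributes
    ----------
    participant_id, sculpture_id : str
        Opaque identifiers.
    ref_image : int
        Viewing-perspective index, 1-8.
    x, y : float
        Position on the reference image, px.
    onset : float
        Time from recording start, ms.
    duration : float
        Fixation duration, ms; strictly positive.
    ordinal : int
        Position within the participant's fixation sequence on this
        sculpture (0-based, consecutive).
    """

    participant_id: str
    sculpture_id: str
    ref_image: int
    x: float
    y: float
    onset: float
    duration: float
    ordinal: int


@dataclass
class ScanPath:
    """Ordered fixation sequence of one participant on one sculpture."""

    participant_id: str
    sculpture_id: str
    fixations: list[Fixation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fixations)

    @property
    def inspection_time(self) -> float:
        """Elapsed ms from onset of the first fixation to the end of the last.

        Zero for an empty scanpath.
        """
        if not self.fixations:
            return 0.0
        first = self.fixations[0]
        last = self.fixations[-1]
        return (last.onset + last.duration) - first.onset

    @property
    def total_fixation_time(self) -> float:
        """Sum of fixation durations, ms (alternative inspection-time basis)."""
        return float(sum(f.duration for f in self.fixations))

    def durations(self) -> list[float]:
        return [f.duration for f in self.fixations]


@dataclass(frozen=True)
class AOIRegion:
    """One basic-feature polygon on one reference image."""

    feature_id: str
    ref_image: int
    vertices: tuple[tuple[float, float], ...]

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class AOISet:
    """Expert-defined basic features (AOIs) for one sculpture.

    The same ``feature_id`` may appear on several reference images: a
    physical feature keeps one identity across viewing perspectives.
    """

    sculpture_id: str
    regions: list[AOIRegion] = field(default_factory=list)

    def feature_ids(self) -> set[str]:
        return {r.feature_id for r in self.regions}

    def regions_for(self, ref_image: int) -> list[AOIRegion]:
        return [r for r in self.regions if r.ref_image == ref_image]


# ---------------------------------------------------------------------------
# Fixation tables
# ---------------------------------------------------------------------------

def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_fixation_table(
    path: str | Path,
    *,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[ScanPath]:
    """Read a delimited fixation table into validated scanpaths.

    Parameters
    ----------
    path
        CSV/TSV file with a header row naming the columns in
        :data:`FIXATION_COLUMNS` (plus optional ``ordinal``).
    delimiter
        Field delimiter; inferred from the extension when omitted.
    column_map
        Optional mapping of file column name -> canonical column name,
        for tables exported with different headers.

    Returns
    -------
    list of ScanPath
        One scanpath per (participant, sculpture), fixations ordered by
        ordinal (file order when the ``ordinal`` column is absent).

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a row violates a fixation invariant (non-positive duration,
        ref_image outside 1-8, negative onset, non-monotone onsets,
        non-consecutive ordinals); the message cites the offending
        1-based data row.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep=_infer_delimiter(path, delimiter),
        dtype={0: str},
        keep_default_na=False,
    )
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in FIXATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    return scanpaths_from_frame(frame, source=path.name)


def scanpaths_from_frame(frame: pd.DataFrame, *, source: str = "<frame>") -> list[ScanPath]:
    """Validate a fixation DataFrame and group it into scanpaths.

    Row numbers in error messages are 1-based positions among the data
    rows of ``frame``.
    """
    has_ordinal = "ordinal" in frame.columns
    rows_by_key: dict[tuple[str, str], list[tuple[int, dict]]] = {}
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        pid = str(row["participant_id"])
        sid = str(row["sculpture_id"])
        try:
            ref_image = int(row["ref_image"])
            x = float(row["x"])
            y = float(row["y"])
            onset = float(row["onset_ms"])
            duration = float(row["duration_ms"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{source}: row {pos}: non-numeric field ({exc})")
        if duration <= 0:
            raise ValidationError(
                f"{source}: row {pos}: duration must be > 0 ms, got {duration}"
            )
        if onset < 0:
            raise ValidationError(
                f"{source}: row {pos}: onset must be >= 0 ms, got {onset}"
            )
        if not 1 <= ref_image <= N_REF_IMAGES:
            raise ValidationError(
                f"{source}: row {pos}: ref_image must be 1-{N_REF_IMAGES}, got {ref_image}"
            )
        rec = {
            "participant_id": pid,
            "sculpture_id": sid,
            "ref_image": ref_image,
            "x": x,
            "y": y,
            "onset": onset,
            "duration": duration,
        }
        if has_ordinal:
            rec["ordinal"] = int(row["ordinal"])
        rows_by_key.setdefault((pid, sid), []).append((pos, rec))

    scanpaths: list[ScanPath] = []
    for (pid, sid), rows in rows_by_key.items():
        if has_ordinal:
            rows = sorted(rows, key=lambda item: item[1]["ordinal"])
            ordinals = [r["ordinal"] for _, r in rows]
            expected = list(range(ordinals[0], ordinals[0] + len(ordinals)))
            if ordinals != expected:
                raise ValidationError(
                    f"{source}: ordinals for ({pid}, {sid}) are not consecutive: {ordinals}"
                )
        fixations = []
        prev_onset = None
        for ordinal, (pos, rec) in enumerate(rows):
            if prev_onset is not None and rec["onset"] < prev_onset:
                raise ValidationError(
                    f"{source}: row {pos}: onset decreases within ({pid}, {sid})"
                )
            prev_onset = rec["onset"]
            fixations.append(
                Fixation(
                    participant_id=pid,
                    sculpture_id=sid,
                    ref_image=rec["ref_image"],
                    x=rec["x"],
                    y=rec["y"],
                    onset=rec["onset"],
                    duration=rec["duration"],
                    ordinal=ordinal,
                )
            )
        scanpaths.append(ScanPath(participant_id=pid, sculpture_id=sid, fixations=fixations))
    return scanpaths


def scanpaths_to_frame(scanpaths: Iterable[ScanPath]) -> pd.DataFrame:
    """Flatten scanpaths back into a canonical fixation DataFrame."""
    records = [
        {
            "participant_id": f.participant_id,
            "sculpture_id": f.sculpture_id,
            "ref_image": f.ref_image,
            "x": f.x,
            "y": f.y,
            "onset_ms": f.onset,
            "duration_ms": f.duration,
            "ordinal": f.ordinal,
        }
        for sp in scanpaths
        for f in sp.fixations
    ]
    return pd.DataFrame.from_records(
        records, columns=list(FIXATION_COLUMNS) + ["ordinal"]
    )


def write_fixation_table(scanpaths: Iterable[ScanPath], path: str | Path) -> None:
    """Write scanpaths as a canonical CSV fixation table."""
    scanpaths_to_frame(scanpaths).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# AOI sets
# ---------------------------------------------------------------------------

def _validate_region(feature_id: str, ref_image: int, vertices: Sequence) -> AOIRegion:
    verts = tuple((float(x), float(y)) for x, y in vertices)
    if len(verts) < 3:
        raise ValidationError(
            f"AOI '{feature_id}' (ref_image {ref_image}): polygon needs >= 3 vertices, "
            f"got {len(verts)}"
        )
    poly = Polygon(verts)
    if not poly.is_valid or poly.area <= 0:
        raise ValidationError(
            f"AOI '{feature_id}' (ref_image {ref_image}): polygon is not simple "
            "(self-intersecting or degenerate)"
        )
    if not 1 <= int(ref_image) <= N_REF_IMAGES:
        raise ValidationError(
            f"AOI '{feature_id}': ref_image must be 1-{N_REF_IMAGES}, got {ref_image}"
        )
    return AOIRegion(feature_id=str(feature_id), ref_image=int(ref_image), vertices=verts)


def aoi_set_from_dict(data: Mapping) -> AOISet:
    """Build a validated :class:`AOISet` from its dict representation."""
    try:
        sculpture_id = str(data["sculpture_id"])
        raw_regions = data["regions"]
    except KeyError as exc:
        raise SchemaError(f"AOI definition missing key: {exc}")
    regions = []
    for entry in raw_regions:
        try:
            regions.append(
                _validate_region(entry["feature_id"], entry["ref_image"], entry["vertices"])
            )
        except KeyError as exc:
            raise SchemaError(f"AOI region missing key: {exc}")
    return AOISet(sculpture_id=sculpture_id, regions=regions)


def aoi_set_to_dict(aoi_set: AOISet) -> dict:
    return {
        "sculpture_id": aoi_set.sculpture_id,
        "regions": [
            {
                "feature_id": r.feature_id,
                "ref_image": r.ref_image,
                "vertices": [[x, y] for x, y in r.vertices],
            }
            for r in aoi_set.regions
        ],
    }


def read_aoi_set(path: str | Path) -> AOISet:
    """Read an AOI set from YAML or JSON (chosen by extension)."""
    path = Path(path)
    with open(path) as handle:
        data = json.load(handle) if path.suffix.lower() == ".json" else yaml.safe_load(handle)
    return aoi_set_from_dict(data)


def write_aoi_set(aoi_set: AOISet, path: str | Path) -> None:
    path = Path(path)
    data = aoi_set_to_dict(aoi_set)
    with open(path, "w") as handle:
        if path.suffix.lower() == ".json":
            json.dump(data, handle, indent=2)
        else:
            yaml.safe_dump(data, handle, sort_keys=False)


# ---------------------------------------------------------------------------
# Participant metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, float]:
    """Read participant metadata CSV -> {participant_id: years_experience}."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    for col in ("participant_id", "years_experience"):
        if col not in frame.columns:
            raise SchemaError(f"{Path(path).name}: missing required column: {col}")
    return {
        str(row.participant_id): float(row.years_experience)
        for row in frame.itertuples()
    }


def write_metadata(meta: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"participant_id": list(meta), "years_experience": list(meta.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summary tables and rounding
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (half-up), e.g. 5306.5 -> 5307.

    Python's built-in ``round`` uses banker's rounding; printed tables
    here use half-up at the table's precision.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def format_ratio(value: float) -> str:
    """Format a ratio or rate with two decimals (half-up)."""
    return f"{round_half_up(value, 2):.2f}"


def format_distance(value: float) -> str:
    """Format a scanpath distance as an integer (half-up)."""
    return f"{round_half_up(value, 0):.0f}"


def write_summary_table(
    rows: Iterable[Mapping],
    path: str | Path,
    *,
    columns: Sequence[str] | None = None,
    formats: Mapping[str, str] | None = None,
) -> None:
    """Write result rows as a CSV with deterministic columns and formatting.

    Parameters
    ----------
    rows
        Mappings sharing a common key set.
    columns
        Explicit column order; inferred from the first row when omitted
        (required when ``rows`` is empty, to emit a header-only file).
    formats
        Optional per-column format: ``"ratio"`` (two decimals, half-up)
        or ``"distance"`` (integer, half-up); other columns are written
        verbatim.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("columns are required to write an empty table")
        columns = list(rows[0].keys())
    formatters = {"ratio": format_ratio, "distance": format_distance}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for row in rows:
            out = []
            for col in columns:
                value = row.get(col, "")
                kind = (formats or {}).get(col)
                if kind is not None and value != "" and pd.notna(value):
                    value = formatters[kind](float(value))
                out.append(value)
            writer.writerow(out)
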