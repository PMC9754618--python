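"""Shared paths and cohort bootstrap for the analysis drivers."""

from pathlib import Path

from scanpath3d import synth
from scanpath3d.io import write_aoi_set, write_metadata

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

COHORT_SEED = 42
SCULPTURE_HEIGHTS = {"moses": 600.0, "daphne": 1050.0}


def ensure_cohort() -> synth.Cohort:
    """Generate (or regenerate) the deterministic study-shaped cohort and
    make sure its files exist under results/data."""
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    cohort = synth.generate_cohort(synth.default_config(COHORT_SEED))
    fix_path = DATA_DIR / "fixations.csv"
    if not fix_path.exists():
        cohort.fixations.to_csv(fix_path, index=False)
        write_metadata(cohort.meta, DATA_DIR / "meta.csv")
        for sid, aoi_set in cohort.aoi_sets.items():
            write_aoi_set(aoi_set, DATA_DIR / f"aois_{sid}.yaml")
    return cohort
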