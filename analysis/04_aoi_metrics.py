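"""Basic-feature coverage and revisit behaviour per expertise level.

Hit-tests every fixation against the expert-defined basic features of
its reference image and summarises, per level: distinct features
fixated, the percentage of fixations on features, and revisits per
minute.
"""

from _common import RESULTS_DIR, ensure_cohort

from scanpath3d import aoi as aoi_mod
from scanpath3d import globallocal as gl
from scanpath3d.io import write_summary_table


def main() -> None:
    cohort = ensure_cohort()
    profiles = cohort.profiles()
    rows = []
    for sid in sorted(cohort.aoi_sets):
        metrics = {
            sp.participant_id: aoi_mod.analyze_scanpath(sp, cohort.aoi_sets[sid])
            for sp in cohort.scanpaths(sid)
        }
        for name, getter in (
            ("n_features_fixated", lambda m: float(m.n_features_fixated)),
            ("pct_on_features", lambda m: m.pct_on_features),
            ("revisits_per_min", lambda m: m.revisits_per_min),
        ):
            values = {pid: getter(m) for pid, m in metrics.items()}
            table = gl.group_summary(values, profiles, metric=name)
            for rec in table.to_dict("records"):
                rows.append({"sculpture_id": sid, **rec})
            total = table.set_index("group").loc["total"]
            print(f"{sid} {name}: total mean {total['mean']:.2f} (SD {total['sd']:.2f})")
    out = RESULTS_DIR / "aoi_metrics_by_level.csv"
    write_summary_table(
        rows, out,
        columns=["sculpture_id", "group", "metric", "n", "mean", "sd"],
        formats={"mean": "ratio", "sd": "ratio"},
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
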