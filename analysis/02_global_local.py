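"""Global/local viewing per expertise level.

Labels every fixation global (<= 187 ms) or local (> 187 ms) and
summarises the global/local ratio and the switching frequency per
expertise level and sculpture.
"""

from _common import RESULTS_DIR, ensure_cohort

from scanpath3d import globallocal as gl
from scanpath3d.io import write_summary_table


def main() -> None:
    cohort = ensure_cohort()
    profiles = cohort.profiles()
    rows = []
    for sid in sorted(cohort.aoi_sets):
        ratios, rates = {}, {}
        for sp in cohort.scanpaths(sid):
            res = gl.analyze_scanpath(sp)
            ratios[sp.participant_id] = res.gl_ratio
            rates[sp.participant_id] = res.switch_rate
        for metric, values in (("gl_ratio", ratios), ("switch_rate_hz", rates)):
            table = gl.group_summary(values, profiles, metric=metric)
            for rec in table.to_dict("records"):
                rows.append({"sculpture_id": sid, **rec})
            total = table.set_index("group").loc["total"]
            print(f"{sid} {metric}: total mean {total['mean']:.2f} (SD {total['sd']:.2f})")
    out = RESULTS_DIR / "globallocal_by_level.csv"
    write_summary_table(
        rows, out,
        columns=["sculpture_id", "group", "metric", "n", "mean", "sd"],
        formats={"mean": "ratio", "sd": "ratio"},
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
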