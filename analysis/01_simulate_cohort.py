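"""Generate the synthetic museum cohort the downstream analyses consume.

Twenty participants — five laypersons, novices, semi-experts and
experts — each view two sculptures from eight perspectives.  Expertise
groups share duration statistics but differ in gaze centre, so scanpath
distance (not the duration metrics) should separate them.
"""

from _common import COHORT_SEED, DATA_DIR, ensure_cohort


def main() -> None:
    cohort = ensure_cohort()
    n_fix = len(cohort.fixations)
    per = cohort.fixations.groupby("sculpture_id").size()
    print(f"seed {COHORT_SEED}: {n_fix} fixations from {len(cohort.meta)} participants")
    for sid, count in per.items():
        features = len(cohort.aoi_sets[sid].feature_ids())
        print(f"  {sid}: {count} fixations, {features} basic features")
    print(f"files under {DATA_DIR}")


if __name__ == "__main__":
    main()
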