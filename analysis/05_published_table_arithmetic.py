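"""Recompute the published tables' self-contained arithmetic.

The study's raw museum recordings are not deposited, but several of its
printed numbers are pure functions of other printed numbers: the
divergence pair counts, the experts' mean years of experience, the
cohort 'Total' rows (means of the four level means, groups being equal
sized) and the pooled divergence means (means of the printed per-cell
distance means).  This driver re-derives all of them through the
package's own aggregation code.
"""

import json
import sys
from pathlib import Path

from _common import RESULTS_DIR

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))
import acceptance  # noqa: E402  (the same arithmetic backs the acceptance report)


def main() -> None:
    results: dict = {}
    acceptance.pair_combinatorics(results)
    acceptance.expert_mean(results)
    acceptance.total_rows(results)
    acceptance.divergence_pooling(results)
    out = RESULTS_DIR / "published_table_arithmetic.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as handle:
        json.dump(results, handle, indent=2)
    print(f"pair counts by divergence: "
          f"{[results[f'pairs_divergence_{d}']['value'] for d in range(4)]}")
    print(f"expert mean experience: {results['expert_mean_years_experience']['value']} years")
    for sid in ("moses", "daphne"):
        pooled = [results[f"distance_divergence{d}_{sid}_px"]["value"] for d in range(4)]
        print(f"{sid} pooled divergence means (px): {pooled}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
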