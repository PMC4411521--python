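#!/usr/bin/env python
"""Score both studies with the rank-based integrated measure.

Each study's trials are pooled (80 ranks for validity, 22 for retest),
ranked by completion time and by error count with midranks, and each
trial receives the sum of its two percent deviations from the mean
rank.  Positive = poorer than the study average.  Writes
results/scored_{validity,retest}.csv and prints the arm summaries.
"""

from pathlib import Path

from startrack.integrated_measure import (
    arm_summaries,
    integrated_measures,
    write_scored_trials,
)
from startrack.report import render_arm_table
from startrack.trial_model import read_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for phase in ("validity", "retest"):
        trials = read_trials(OUT / f"trials_{phase}.csv")
        scored = integrated_measures(trials)
        write_scored_trials(scored, OUT / f"scored_{phase}.csv")
        total = sum(s.im for s in scored)
        print(f"{phase}: scored {len(scored)} pooled trials "
              f"(integrated measures sum to {total:+.1e})")
        print(render_arm_table(arm_summaries(scored)))
        print()
    print(f"Wrote scored_validity.csv and scored_retest.csv under {OUT}")


if __name__ == "__main__":
    main()
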