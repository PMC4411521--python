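#!/usr/bin/env python
"""Draw the blinded crossover allocation for the validity study.

Each of the 20 subjects receives the four conditions (baseline, fatigue,
stress, fatigue+stress) exactly once, in an independently randomized
order, with sessions two days apart labeled day 1 / day 4 / day 7 /
day 10 for the sealed envelopes.  Writes results/schedule.csv.
"""

import argparse
from pathlib import Path

from startrack.randomization import envelope_labels, generate_schedule

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20250)
    parser.add_argument("--subjects", type=int, default=20)
    args = parser.parse_args()

    schedule = generate_schedule(args.subjects, args.seed)
    table = envelope_labels(schedule)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "schedule.csv", index=False)
    counts = table.groupby("condition").size()
    print(f"Randomized {args.subjects} subjects (seed {args.seed}):")
    print(f"  {len(table)} sealed envelopes, conditions balanced at")
    print("  " + ", ".join(f"{c}={n}" for c, n in counts.items()))
    print(f"Wrote {OUT / 'schedule.csv'}")


if __name__ == "__main__":
    main()
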