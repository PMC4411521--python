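#!/usr/bin/env python
"""Simulate both studies: the 20x4 crossover and the 11x2 retest.

Uses the calibrated synthetic performance model (lognormal times,
overdispersed error counts, correlated subject effects) with the
allocation drawn in step 02.  Writes results/trials_validity.csv and
results/trials_retest.csv.
"""

import argparse
import dataclasses
from pathlib import Path

from startrack.randomization import generate_schedule
from startrack.synthetic_data import (
    SimulationConfig,
    simulate_retest_study,
    simulate_validity_study,
)
from startrack.trial_model import write_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20250)
    args = parser.parse_args()

    validity_cfg = SimulationConfig(n_subjects=20, seed=args.seed)
    retest_cfg = SimulationConfig(n_subjects=11, seed=args.seed + 1)
    schedule = generate_schedule(20, args.seed)

    validity = simulate_validity_study(validity_cfg, schedule)
    retest = simulate_retest_study(retest_cfg)
    OUT.mkdir(exist_ok=True)
    write_trials(validity, OUT / "trials_validity.csv")
    write_trials(retest, OUT / "trials_retest.csv")

    times = [t.completion_time_s for t in validity]
    errors = [t.error_count for t in validity]
    print(f"Validity study: {len(validity)} trials over 20 subjects x 4 conditions")
    print(f"  completion times {min(times):.0f}-{max(times):.0f} s, "
          f"errors {min(errors)}-{max(errors)}")
    print(f"Retest study: {len(retest)} trials over 11 subjects x 2 sessions")
    print(f"Wrote trials_validity.csv and trials_retest.csv under {OUT}")


if __name__ == "__main__":
    main()
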