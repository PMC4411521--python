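#!/usr/bin/env python
"""Test-retest reliability of the integrated measure.

Pearson correlation between the two sessions' per-subject scores, a
paired t-test screening for a learning effect, and per-session
normality checks.  Writes results/reliability.json.
"""

from pathlib import Path

from startrack.reliability import analyze_retest
from startrack.report import render_reliability, result_to_json
from startrack.trial_model import read_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(OUT / "trials_retest.csv")
    result = analyze_retest(trials)
    (OUT / "reliability.json").write_text(result_to_json(result) + "\n")
    print(render_reliability(result))
    print()
    verdict = "strong" if result.r >= 0.8 else "moderate" if result.r >= 0.6 else "weak"
    print(f"Session-to-session correlation is {verdict} (r = {result.r:.2f}); "
          f"the paired t-test (p = {result.p_paired:.2f}) shows "
          f"{'no' if result.p_paired > 0.05 else 'a'} systematic session difference.")
    print(f"Wrote {OUT / 'reliability.json'}")


if __name__ == "__main__":
    main()
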