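#!/usr/bin/env python
"""Construct validity of the star-track test under the crossover design.

Shapiro-Wilk normality per arm, Mauchly's sphericity test, one-way
repeated-measures ANOVA over the four conditions, and Bonferroni
post-hoc pairwise comparisons with family-wise confidence intervals.
Writes results/validity.json and results/validity_tables.txt.
"""

from pathlib import Path

from startrack.report import render_validity, result_to_json
from startrack.trial_model import read_trials
from startrack.validity import analyze_validity

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(OUT / "trials_validity.csv")
    result = analyze_validity(trials)
    (OUT / "validity.json").write_text(result_to_json(result) + "\n")
    text = render_validity(result)
    (OUT / "validity_tables.txt").write_text(text + "\n")
    print(text)
    print()
    baseline_contrasts = [c for c in result.posthoc if c.pair[0] == "baseline"]
    n_sig = sum(c.p_bonferroni < 0.05 for c in baseline_contrasts)
    print(f"ANOVA: conditions differ (p = {result.anova_p:.4f}); "
          f"{n_sig}/3 baseline-vs-intervention contrasts significant after "
          f"Bonferroni correction.")
    print(f"Wrote validity.json and validity_tables.txt under {OUT}")


if __name__ == "__main__":
    main()
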