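"""Human-readable and JSON renderings of analysis results.

JSON is the canonical machine output; the text tables mirror the
conventional reporting layout of a crossover validation (arm, N, mean
integrated measure, SD; pairwise mean differences with CI and p), and
the figure-style summary renders scores as percent from the study mean
with SD whiskers.  Rendering is a pure function of the result objects.
"""

from __future__ import annotations

import json
import math
from typing import Sequence

from .integrated_measure import ArmSummary
from .reliability import ReliabilityResult
from .validity import PairwiseComparison, ValidityResult

__all__ = [
    "render_arm_table",
    "render_posthoc_table",
    "render_validity",
    "render_reliability",
    "render_percent_summary",
    "result_to_json",
]

_ARM_TITLES = {
    "baseline": "Baseline",
    "fatigue": "Fatigue",
    "stress": "Stress",
    "fatigue_stress": "Fatigue + stress",
    "day1": "Test day 1",
    "day2": "Test day 2",
}


def _fmt(x: float, nd: int = 2) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "n/a"
    return f"{x:.{nd}f}"


def render_arm_table(arms: Sequence[ArmSummary]) -> str:
    """Arm-level table: condition, N, mean integrated measure, SD."""
    if not arms:
        raise ValueError("nothing to render: no arm summaries")
    rows = [("Test arm", "N", "Integrated measure", "SD")]
    for a in arms:
        rows.append(
            (_ARM_TITLES.get(a.condition, a.condition), str(a.n), _fmt(a.mean_im), _fmt(a.sd_im))
        )
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
    )


def render_posthoc_table(posthoc: Sequence[PairwiseComparison]) -> str:
    """Pairwise table: comparison, mean difference (95% CI), p."""
    if not posthoc:
        raise ValueError("nothing to render: no post-hoc comparisons")
    rows = [("Comparison", "Mean difference (95% CI)", "p")]
    for c in posthoc:
        a = _ARM_TITLES.get(c.pair[0], c.pair[0])
        b = _ARM_TITLES.get(c.pair[1], c.pair[1])
        rows.append(
            (
                f"{a} - {b}",
                f"{_fmt(c.mean_difference)} ({_fmt(c.ci_low)}; {_fmt(c.ci_high)})",
                _fmt(c.p_bonferroni),
            )
        )
    widths = [max(len(r[i]) for r in rows) for i in range(3)]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
    )


def render_percent_summary(arms: Sequence[ArmSummary]) -> str:
    """Figure-style summary: mean score x 100 (percent from study mean)
    with SD whiskers."""
    if not arms:
        raise ValueError("nothing to render: no arm summaries")
    lines = ["Integrated measure, percent from study mean (mean +/- SD):"]
    for a in arms:
        sd = "n/a" if math.isnan(a.sd_im) else f"{100 * a.sd_im:.0f}"
        lines.append(
            f"  {_ARM_TITLES.get(a.condition, a.condition):<16} "
            f"{100 * a.mean_im:+.0f}% +/- {sd}%"
        )
    return "\n".join(lines)


def render_validity(result: ValidityResult) -> str:
    """Full text report of a construct-validity analysis."""
    parts = [
        "Construct validity (randomized crossover)",
        "",
        render_arm_table(result.arms),
        "",
        f"Mauchly's test of sphericity: W = {result.mauchly_W:.3f}, "
        f"chi2({result.mauchly_df}) = {result.mauchly_chi2:.2f}, "
        f"p = {result.mauchly_p:.2f}",
        f"Repeated-measures ANOVA: F({result.anova_df[0]}, {result.anova_df[1]}) "
        f"= {result.anova_F:.2f}, p = {result.anova_p:.3f}",
        "",
        render_posthoc_table(result.posthoc),
        "",
        render_percent_summary(result.arms),
    ]
    return "\n".join(parts)


def render_reliability(result: ReliabilityResult) -> str:
    """Full text report of a test-retest analysis."""
    arms = [
        ArmSummary("day1", result.n, result.mean_im_day1, result.sd_day1),
        ArmSummary("day2", result.n, result.mean_im_day2, result.sd_day2),
    ]
    parts = [
        "Test-retest reliability",
        "",
        render_arm_table(arms),
        "",
        f"Pearson correlation: r = {result.r:.2f}, n = {result.n}, "
        f"p = {result.p_r:.4f}",
        f"Paired t-test (learning effect): t = {result.t_paired:.2f}, "
        f"p = {result.p_paired:.2f}",
    ]
    return "\n".join(parts)


def result_to_json(result: ValidityResult | ReliabilityResult) -> str:
    """Canonical JSON rendering of a result object (sorted keys)."""
    return json.dumps(result.to_dict(), indent=2, sort_keys=True, allow_nan=True)
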