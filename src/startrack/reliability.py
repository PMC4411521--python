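"""Test-retest reliability of the integrated measure.

The two sessions of every subject are pooled (2n trials, 2n ranks),
scored, and compared: Pearson product-moment correlation between the
per-subject session scores, a paired t-test to screen for a systematic
session difference (learning effect), and Shapiro-Wilk normality checks
per session.  All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .integrated_measure import arm_summaries, integrated_measures
from .trial_model import RETEST_CONDITIONS, TrialRecord

__all__ = [
    "ReliabilityResult",
    "pearson_r",
    "paired_t",
    "shapiro_wilk",
    "analyze_retest",
]


@dataclass(frozen=True)
class ReliabilityResult:
    """Full test-retest analysis output."""

    n: int
    r: float
    p_r: float
    t_paired: float
    p_paired: float
    shapiro_p_day1: float
    shapiro_p_day2: float
    mean_im_day1: float
    mean_im_day2: float
    sd_day1: float
    sd_day2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its exact-t two-sided p.

    Requires n >= 3 paired observations and non-zero variance in both
    variables (the correlation is undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired-samples t-test on the differences x - y.

    Identical inputs give (t=0, p=1); constant non-zero differences have
    zero variance and no finite t, which raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError(f"need at least 2 pairs for a paired t-test, got {x.size}")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError(
            "degenerate paired t-test: constant non-zero differences "
            "(zero variance)"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation), for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _session_pairs(trials: Sequence[TrialRecord]) -> list[str]:
    """Validate day1/day2 pairing and return subjects in stable id order."""
    seen: dict[str, set[str]] = {}
    for t in trials:
        seen.setdefault(t.subject_id, set())
        if t.condition in seen[t.subject_id]:
            raise ValueError(
                f"subject {t.subject_id!r} has more than one {t.condition} trial"
            )
        seen[t.subject_id].add(t.condition)
    unpaired = [s for s, conds in seen.items() if conds != set(RETEST_CONDITIONS)]
    if unpaired:
        raise ValueError(
            f"subjects without a complete day1/day2 pair: {sorted(unpaired)}"
        )
    return sorted(seen)


def analyze_retest(trials: Sequence[TrialRecord]) -> ReliabilityResult:
    """Run the full test-retest analysis on a retest study's trials.

    Integrated measures are computed over all 2n pooled trials; the
    correlation and the paired t-test act on the per-subject
    (day1, day2) score pairs.
    """
    if any(t.phase != "retest" for t in trials):
        raise ValueError("analyze_retest expects retest-phase trials only")
    subjects = _session_pairs(trials)
    scored = integrated_measures(list(trials))
    by_cell = {(s.trial.subject_id, s.trial.condition): s.im for s in scored}
    day1 = np.array([by_cell[(s, "day1")] for s in subjects])
    day2 = np.array([by_cell[(s, "day2")] for s in subjects])
    r, p_r = pearson_r(day1, day2)
    t, p_t = paired_t(day1, day2)
    sw1 = shapiro_wilk(day1)
    sw2 = shapiro_wilk(day2)
    return ReliabilityResult(
        n=len(subjects),
        r=r,
        p_r=p_r,
        t_paired=t,
        p_paired=p_t,
        shapiro_p_day1=sw1[1],
        shapiro_p_day2=sw2[1],
        mean_im_day1=float(day1.mean()),
        mean_im_day2=float(day2.mean()),
        sd_day1=float(np.std(day1, ddof=1)) if len(subjects) > 1 else math.nan,
        sd_day2=float(np.std(day2, ddof=1)) if len(subjects) > 1 else math.nan,
    )
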