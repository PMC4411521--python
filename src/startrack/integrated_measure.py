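"""Rank-based integrated measure of speed and accuracy.

All completed trials of a study are pooled and ranked twice: once by
completion time (faster = lower rank) and once by error count (fewer =
lower rank), with midranks for ties.  For a study of N trials the mean
rank is (N + 1)/2, and each trial's integrated measure is the sum of the
two percent deviations of its ranks from the mean rank::

    im = (rank_time - mean_rank)/mean_rank + (rank_error - mean_rank)/mean_rank

A positive score is poorer than average performance (slower and/or more
error-prone), a negative score better than average.  Midranks keep the
rank total at N(N+1)/2, so the integrated measures of a study always sum
to zero and each lies in [-2(N-1)/(N+1), +2(N-1)/(N+1)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .trial_model import (
    RETEST_CONDITIONS,
    VALIDITY_CONDITIONS,
    TrialRecord,
)

__all__ = [
    "ScoredTrial",
    "ArmSummary",
    "rank_with_midranks",
    "integrated_measures",
    "arm_summaries",
    "write_scored_trials",
]


@dataclass(frozen=True)
class ScoredTrial:
    """A trial together with its ranks and integrated measure."""

    trial: TrialRecord
    rank_time: float
    rank_error: float
    im: float


@dataclass(frozen=True)
class ArmSummary:
    """Per-condition summary of integrated measures (mean and sample SD).

    ``sd_im`` is the n-1 sample standard deviation; it is NaN for a
    single-trial arm, where spread is undefined.
    """

    condition: str
    n: int
    mean_im: float
    sd_im: float


def rank_with_midranks(values: Sequence[float]) -> np.ndarray:
    """Ascending ranks with ties assigned the mean of their positions.

    The rank total is always N(N+1)/2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty list")
    return rankdata(arr, method="average")


def integrated_measures(trials: Sequence[TrialRecord]) -> list[ScoredTrial]:
    """Score every trial of one study against the pooled study ranks.

    All trials must belong to a single phase (the ranks of the validity
    study pool its 80 trials; the retest study pools its 22) and there
    must be at least two of them.  Input order is preserved.
    """
    if len(trials) < 2:
        raise ValueError(f"need at least 2 trials to rank a study, got {len(trials)}")
    phases = {t.phase for t in trials}
    if len(phases) > 1:
        raise ValueError(
            f"trials mix phases {sorted(phases)}; rank each study separately"
        )
    n = len(trials)
    mean_rank = (n + 1) / 2
    rank_time = rank_with_midranks([t.completion_time_s for t in trials])
    rank_error = rank_with_midranks([t.error_count for t in trials])
    scored = []
    for t, rt, re_ in zip(trials, rank_time, rank_error):
        im = (rt - mean_rank) / mean_rank + (re_ - mean_rank) / mean_rank
        scored.append(ScoredTrial(trial=t, rank_time=float(rt), rank_error=float(re_), im=float(im)))
    return scored


def _condition_order(conditions: Iterable[str]) -> list[str]:
    present = list(dict.fromkeys(conditions))
    for canonical in (VALIDITY_CONDITIONS, RETEST_CONDITIONS):
        if set(present) <= set(canonical):
            return [c for c in canonical if c in present]
    return present


def arm_summaries(scored: Sequence[ScoredTrial]) -> list[ArmSummary]:
    """Mean and sample SD of the integrated measure per condition present."""
    if not scored:
        raise ValueError("no scored trials")
    order = _condition_order(s.trial.condition for s in scored)
    out = []
    for cond in order:
        ims = np.array([s.im for s in scored if s.trial.condition == cond])
        sd = float(np.std(ims, ddof=1)) if ims.size > 1 else math.nan
        out.append(
            ArmSummary(condition=cond, n=int(ims.size), mean_im=float(ims.mean()), sd_im=sd)
        )
    return out


def write_scored_trials(scored: Sequence[ScoredTrial], path: str | Path) -> None:
    """Write scored trials as the trials CSV plus rank/im columns."""
    import csv

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            [
                "subject_id",
                "phase",
                "condition",
                "completion_time_s",
                "error_count",
                "rank_time",
                "rank_error",
                "im",
            ]
        )
        for s in scored:
            t = s.trial
            writer.writerow(
                [
                    t.subject_id,
                    t.phase,
                    t.condition,
                    f"{t.completion_time_s:.3f}",
                    t.error_count,
                    f"{s.rank_time:g}",
                    f"{s.rank_error:g}",
                    f"{s.im:.10g}",
                ]
            )
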