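"""Blinded crossover allocation for the four-arm validity study.

Each subject completes all four conditions, never the same one twice,
in an independently randomized order (simple randomization; a balanced
Williams Latin-square option exists behind a flag).  Positions 1-4 map
to the envelope labels "day 1", "day 4", "day 7" and "day 10" — the four
sessions separated by two days' pause.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trial_model import VALIDITY_CONDITIONS

__all__ = ["CrossoverSchedule", "generate_schedule", "envelope_labels", "DAY_LABELS"]

DAY_LABELS = ("day 1", "day 4", "day 7", "day 10")

# Williams design for four treatments: each treatment once per row,
# once per column, and each ordered pair of neighbours once.
_WILLIAMS_4 = ((0, 1, 3, 2), (1, 2, 0, 3), (2, 3, 1, 0), (3, 0, 2, 1))


@dataclass(frozen=True)
class CrossoverSchedule:
    """Per-subject randomized order of the four validity conditions."""

    orders: dict[str, tuple[str, str, str, str]]
    seed: int

    def __post_init__(self) -> None:
        for subject, seq in self.orders.items():
            if sorted(seq) != sorted(VALIDITY_CONDITIONS):
                raise ValueError(
                    f"subject {subject!r}: order {seq} is not a permutation "
                    f"of {VALIDITY_CONDITIONS}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.orders)


def _subject_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_schedule(
    n_subjects: int, seed: int, latin_square: bool = False
) -> CrossoverSchedule:
    """Randomize each subject's order of the four conditions.

    With ``latin_square=True`` subjects are assigned rows of a Williams
    square (columns balanced over conditions) whose treatment labelling
    is shuffled by the seed; the default is independent uniform
    permutations per subject.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    rng = np.random.default_rng(seed)
    orders: dict[str, tuple[str, str, str, str]] = {}
    if latin_square:
        labels = [VALIDITY_CONDITIONS[i] for i in rng.permutation(4)]
        for i, subject in enumerate(_subject_ids(n_subjects)):
            row = _WILLIAMS_4[i % 4]
            orders[subject] = tuple(labels[j] for j in row)
    else:
        for subject in _subject_ids(n_subjects):
            perm = rng.permutation(4)
            orders[subject] = tuple(VALIDITY_CONDITIONS[j] for j in perm)
    return CrossoverSchedule(orders=orders, seed=seed)


def envelope_labels(schedule: CrossoverSchedule) -> pd.DataFrame:
    """Allocation table mapping each subject's session days to conditions.

    One row per sealed envelope: ``subject_id, day_label, condition``,
    with positions 1-4 labelled per :data:`DAY_LABELS`.
    """
    rows = [
        {"subject_id": subject, "day_label": DAY_LABELS[pos], "condition": cond}
        for subject, seq in schedule.orders.items()
        for pos, cond in enumerate(seq)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "day_label", "condition"])


def write_schedule(schedule: CrossoverSchedule, path: str | Path) -> None:
    """Write the labeled allocation table as CSV."""
    envelope_labels(schedule).to_csv(path, index=False)
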