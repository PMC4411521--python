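"""Core data types and text formats for star-track trials.

A *trial* is one completed attempt at the star-shaped track: the subject
traces the track ten times (five clockwise, five counterclockwise) with a
pair of scissors while the apparatus registers the completion time in
seconds and the number of times the scissors touch the track border
(errors).  Two on-disk representations are supported:

* a trials CSV (one row per completed attempt, header
  ``subject_id,phase,condition,completion_time_s,error_count``), and
* the line-oriented STARTRACK v1 event-log dialect for a single raw
  attempt (start/error/end timestamps).

Times are stored in seconds at millisecond precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PHASES",
    "VALIDITY_CONDITIONS",
    "RETEST_CONDITIONS",
    "TrialRecord",
    "EventLog",
    "TrialParseError",
    "EventLogParseError",
    "read_trials",
    "write_trials",
    "read_event_log",
    "write_event_log",
    "summarize_event_log",
]

PHASES = ("retest", "validity")

#: Conditions of the construct-validity crossover: a rested baseline, a
#: physical-fatigue arm, a cognitive-stress (dual-task) arm and their
#: combination.
VALIDITY_CONDITIONS = ("baseline", "fatigue", "stress", "fatigue_stress")

#: Conditions of the test-retest study: two identical sessions.
RETEST_CONDITIONS = ("day1", "day2")

_CONDITIONS_BY_PHASE = {
    "validity": VALIDITY_CONDITIONS,
    "retest": RETEST_CONDITIONS,
}

TRIALS_CSV_HEADER = (
    "subject_id",
    "phase",
    "condition",
    "completion_time_s",
    "error_count",
)


class TrialParseError(ValueError):
    """A trials CSV file violates the format or a record invariant."""


class EventLogParseError(ValueError):
    """A STARTRACK v1 event log violates the dialect or an invariant."""


def _round_ms(t: float) -> float:
    return round(float(t), 3)


@dataclass(frozen=True, order=True)
class TrialRecord:
    """One completed star-track attempt.

    Parameters
    ----------
    subject_id:
        Opaque subject identifier.
    phase:
        ``"validity"`` or ``"retest"``; decides which conditions are legal.
    condition:
        One of :data:`VALIDITY_CONDITIONS` or :data:`RETEST_CONDITIONS`.
    completion_time_s:
        Positive completion time in seconds (stored at ms precision).
    error_count:
        Non-negative integer number of border contacts.
    """

    subject_id: str
    phase: str
    condition: str
    completion_time_s: float
    error_count: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        legal = _CONDITIONS_BY_PHASE[self.phase]
        if self.condition not in legal:
            raise ValueError(
                f"condition {self.condition!r} is not legal for phase "
                f"{self.phase!r} (expected one of {legal})"
            )
        t = _round_ms(self.completion_time_s)
        if not t > 0:
            raise ValueError(f"completion_time_s must be > 0, got {self.completion_time_s}")
        object.__setattr__(self, "completion_time_s", t)
        e = self.error_count
        if isinstance(e, bool) or int(e) != e or int(e) < 0:
            raise ValueError(f"error_count must be a non-negative integer, got {e!r}")
        object.__setattr__(self, "error_count", int(e))


@dataclass(frozen=True)
class EventLog:
    """Raw timestamped record of a single star-track attempt."""

    subject_id: str
    condition: str
    rounds: int
    start_s: float
    error_times_s: tuple[float, ...]
    end_s: float

    def __post_init__(self) -> None:
        if int(self.rounds) != self.rounds or self.rounds < 1:
            raise ValueError(f"rounds must be a positive integer, got {self.rounds!r}")
        object.__setattr__(self, "rounds", int(self.rounds))
        object.__setattr__(self, "start_s", _round_ms(self.start_s))
        object.__setattr__(self, "end_s", _round_ms(self.end_s))
        object.__setattr__(
            self, "error_times_s", tuple(_round_ms(t) for t in self.error_times_s)
        )
        if not self.end_s > self.start_s:
            raise ValueError(
                f"end ({self.end_s}) must be after start ({self.start_s})"
            )
        prev = self.start_s
        for t in self.error_times_s:
            if t < prev:
                raise ValueError(
                    "error times must be non-decreasing and inside [start, end]"
                )
            prev = t
        if self.error_times_s and self.error_times_s[-1] > self.end_s:
            raise ValueError("error time after end of attempt")

    def shifted(self, offset_s: float) -> "EventLog":
        """Return a copy with all timestamps translated by ``offset_s``."""
        return replace(
            self,
            start_s=self.start_s + offset_s,
            end_s=self.end_s + offset_s,
            error_times_s=tuple(t + offset_s for t in self.error_times_s),
        )


def summarize_event_log(log: EventLog) -> tuple[float, int]:
    """Derive ``(completion_time_s, error_count)`` from a raw event log.

    Completion time is ``end - start``; the error count is the number of
    registered border contacts.  The result is invariant to translating
    all timestamps by a constant.
    """
    return _round_ms(log.end_s - log.start_s), len(log.error_times_s)


# ---------------------------------------------------------------------------
# trials CSV

def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trials CSV, validating every row.

    Raises :class:`TrialParseError` naming the offending row for missing
    or extra columns, non-numeric times, negative or fractional error
    counts, and conditions that are illegal for the row's phase.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrialParseError(f"{path}: empty file, expected header") from None
        if tuple(header) != TRIALS_CSV_HEADER:
            missing = set(TRIALS_CSV_HEADER) - set(header)
            extra = set(header) - set(TRIALS_CSV_HEADER)
            raise TrialParseError(
                f"{path}: bad header (missing columns {sorted(missing)}, "
                f"unexpected columns {sorted(extra)})"
            )
        trials: list[TrialRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIALS_CSV_HEADER):
                raise TrialParseError(
                    f"{path}, row {lineno}: expected "
                    f"{len(TRIALS_CSV_HEADER)} fields, got {len(row)}"
                )
            subject_id, phase, condition, time_s, errors = row
            try:
                time_val = float(time_s)
            except ValueError:
                raise TrialParseError(
                    f"{path}, row {lineno}: non-numeric completion_time_s {time_s!r}"
                ) from None
            try:
                error_val = int(errors)
            except ValueError:
                raise TrialParseError(
                    f"{path}, row {lineno}: error_count must be an integer, "
                    f"got {errors!r}"
                ) from None
            try:
                trials.append(
                    TrialRecord(subject_id, phase, condition, time_val, error_val)
                )
            except ValueError as exc:
                raise TrialParseError(f"{path}, row {lineno}: {exc}") from None
    return trials


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    """Write a trials CSV; ``read_trials`` of the result reproduces the input."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TRIALS_CSV_HEADER)
        for t in trials:
            writer.writerow(
                [
                    t.subject_id,
                    t.phase,
                    t.condition,
                    f"{t.completion_time_s:.3f}",
                    t.error_count,
                ]
            )


# ---------------------------------------------------------------------------
# STARTRACK v1 event logs

_MAGIC = "#STARTRACK v1"


def read_event_log(path: str | Path) -> EventLog:
    """Parse a STARTRACK v1 event log file."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    if not lines or lines[0] != _MAGIC:
        raise EventLogParseError(f"{path}: missing '{_MAGIC}' header line")
    fields: dict[str, str] = {}
    errors: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        try:
            key, value = line.split(maxsplit=1)
        except ValueError:
            raise EventLogParseError(f"{path}, line {lineno}: malformed line {line!r}")
        if key == "error":
            try:
                errors.append(float(value))
            except ValueError:
                raise EventLogParseError(
                    f"{path}, line {lineno}: non-numeric error time {value!r}"
                ) from None
        elif key in ("subject", "condition", "rounds", "start", "end"):
            if key in fields:
                raise EventLogParseError(f"{path}, line {lineno}: duplicate '{key}'")
            fields[key] = value
        else:
            raise EventLogParseError(f"{path}, line {lineno}: unknown key {key!r}")
    for key in ("subject", "condition", "rounds", "start", "end"):
        if key not in fields:
            raise EventLogParseError(f"{path}: missing '{key}' line")
    try:
        log = EventLog(
            subject_id=fields["subject"],
            condition=fields["condition"],
            rounds=int(fields["rounds"]),
            start_s=float(fields["start"]),
            error_times_s=tuple(errors),
            end_s=float(fields["end"]),
        )
    except ValueError as exc:
        raise EventLogParseError(f"{path}: {exc}") from None
    return log


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write a STARTRACK v1 event log; round-trips through ``read_event_log``."""
    path = Path(path)
    lines = [
        _MAGIC,
        f"subject {log.subject_id}",
        f"condition {log.condition}",
        f"rounds {log.rounds}",
        f"start {log.start_s:.3f}",
        *[f"error {t:.3f}" for t in log.error_times_s],
        f"end {log.end_s:.3f}",
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
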