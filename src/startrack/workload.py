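"""Multiple-resources (3-D+1) dual-task interference score.

Used to design the cognitive-stress intervention: while tracing the
star track the subject identifies playing cards shown one per round.
Interference between two concurrent tasks is scored on a 0-8 scale as
the sum of a demand component and a resource-conflict component::

    score = demand(a) + demand(b) + |resources(a) & resources(b)|

Each task's demand is 0 (automatic), 1 (simple) or 2 (difficult), so
demands contribute 0-4; the conflict term counts shared resource
dimensions out of the 3-D+1 set {perception, cognition, response,
visual_channel}, contributing 0-4.  The star-track-plus-card pairing —
two simple tasks sharing perception and cognition — scores 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import FrozenSet, Iterable

__all__ = [
    "Demand",
    "RESOURCE_DIMENSIONS",
    "TaskProfile",
    "interference_score",
    "STAR_TRACK_TASK",
    "CARD_IDENTIFICATION_TASK",
]


class Demand(IntEnum):
    """Task difficulty level; the numeric value is the demand load."""

    AUTOMATIC = 0
    SIMPLE = 1
    DIFFICULT = 2


RESOURCE_DIMENSIONS = frozenset(
    {"perception", "cognition", "response", "visual_channel"}
)


@dataclass(frozen=True)
class TaskProfile:
    """A task's demand level and the resource dimensions it loads."""

    demand: Demand
    resources: FrozenSet[str]

    def __post_init__(self) -> None:
        res = frozenset(self.resources)
        unknown = res - RESOURCE_DIMENSIONS
        if unknown:
            raise ValueError(
                f"unknown resource dimensions {sorted(unknown)}; "
                f"expected a subset of {sorted(RESOURCE_DIMENSIONS)}"
            )
        if self.demand != Demand.AUTOMATIC and not res:
            raise ValueError("a non-automatic task must load at least one resource")
        object.__setattr__(self, "resources", res)
        object.__setattr__(self, "demand", Demand(self.demand))


def interference_score(a: TaskProfile, b: TaskProfile) -> int:
    """Total dual-task interference of two concurrent tasks, 0-8.

    Symmetric, and monotone in both demands and in the shared-resource
    set.
    """
    return int(a.demand) + int(b.demand) + len(a.resources & b.resources)


#: Following the star track: visually perceived, spatially understood,
#: answered with a manual response.
STAR_TRACK_TASK = TaskProfile(
    demand=Demand.SIMPLE,
    resources=frozenset({"perception", "cognition", "response"}),
)

#: Naming the rank and suit of a card held in the same field of vision.
CARD_IDENTIFICATION_TASK = TaskProfile(
    demand=Demand.SIMPLE,
    resources=frozenset({"perception", "cognition"}),
)
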