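#!/usr/bin/env python
"""Score the dual-task interference that motivates the stress intervention.

Tracing the star track is a simple task loading perception, cognition and
a manual response; identifying playing cards held in the same field of
vision is a simple task loading perception and cognition.  The
multiple-resources interference of running them concurrently quantifies
how hard the combination should press on the subject's mental workload.
Writes results/interference.json.
"""

import json
from pathlib import Path

from startrack.workload import (
    CARD_IDENTIFICATION_TASK,
    STAR_TRACK_TASK,
    interference_score,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    score = interference_score(STAR_TRACK_TASK, CARD_IDENTIFICATION_TASK)
    summary = {
        "task_a": {
            "name": "star-track tracing",
            "demand": STAR_TRACK_TASK.demand.name.lower(),
            "resources": sorted(STAR_TRACK_TASK.resources),
        },
        "task_b": {
            "name": "card identification",
            "demand": CARD_IDENTIFICATION_TASK.demand.name.lower(),
            "resources": sorted(CARD_IDENTIFICATION_TASK.resources),
        },
        "shared_resources": sorted(
            STAR_TRACK_TASK.resources & CARD_IDENTIFICATION_TASK.resources
        ),
        "interference_score": score,
        "scale": [0, 8],
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "interference.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"Dual-task interference of star-track + card identification: "
        f"{score} on the 0-8 scale\n"
        f"  (demands {int(STAR_TRACK_TASK.demand)} + "
        f"{int(CARD_IDENTIFICATION_TASK.demand)}, shared resources "
        f"{', '.join(summary['shared_resources'])})"
    )
    print("A mid-scale interference: enough concurrent load to stress the")
    print("subject without making the combined task impossible.")


if __name__ == "__main__":
    main()
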