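"""Ethogram definitions shared across the pipeline.

The seven-class ethogram used for sea-turtle bio-logging (Breathing, Feeding,
Gliding, Resting, Scratching, Swimming, plus a catch-all Other) and the
UNLABELED sentinel used for samples with no video annotation.
"""

from __future__ import annotations

from enum import IntEnum


class Behavior(IntEnum):
    """Integer-coded behavior classes; codes index network output channels."""

    BREATHING = 0
    FEEDING = 1
    GLIDING = 2
    RESTING = 3
    SCRATCHING = 4
    SWIMMING = 5
    OTHER = 6


#: Sentinel label for timesteps with no annotation (e.g. night sequences).
UNLABELED: int = -1

#: All behavior classes in channel order.
ALL_BEHAVIORS: tuple[Behavior, ...] = tuple(Behavior)

#: Name lookup used by file I/O ("U" marks unlabeled samples on disk).
NAME_TO_CODE: dict[str, int] = {b.name: int(b) for b in Behavior}
NAME_TO_CODE["UNLABELED"] = UNLABELED
CODE_TO_NAME: dict[int, str] = {v: k for k, v in NAME_TO_CODE.items()}
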