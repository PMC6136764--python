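"""The nine wrist-motion classes decoded by the system.

Four primitive wrist motions (flexion, extension, pronation, supination)
plus their four non-antagonist pairings and a rest class.  Combined
classes are first-class labels: simultaneous control is achieved by
classifying a combined contraction as its own class, not by mixing two
single-motion decisions.
"""

from __future__ import annotations

from enum import Enum


class MotionClass(str, Enum):
    NO_MOTION = "no_motion"
    FLEXION = "flexion"
    EXTENSION = "extension"
    PRONATION = "pronation"
    SUPINATION = "supination"
    EXT_PRO = "ext_pro"
    EXT_SUP = "ext_sup"
    FLX_PRO = "flx_pro"
    FLX_SUP = "flx_sup"

    @property
    def primitives(self) -> tuple["MotionClass", ...]:
        """Constituent primitive motions (empty for rest, two for combos)."""
        return _PRIMITIVES[self]

    @property
    def is_combined(self) -> bool:
        return len(self.primitives) == 2


PRIMITIVE_CLASSES = (
    MotionClass.FLEXION,
    MotionClass.EXTENSION,
    MotionClass.PRONATION,
    MotionClass.SUPINATION,
)

#: the 8 classes that move the cursor, in a stable canonical order
ACTIVE_CLASSES = (
    MotionClass.FLEXION,
    MotionClass.EXTENSION,
    MotionClass.PRONATION,
    MotionClass.SUPINATION,
    MotionClass.EXT_PRO,
    MotionClass.EXT_SUP,
    MotionClass.FLX_PRO,
    MotionClass.FLX_SUP,
)

ALL_CLASSES = (MotionClass.NO_MOTION,) + ACTIVE_CLASSES

_PRIMITIVES: dict[MotionClass, tuple[MotionClass, ...]] = {
    MotionClass.NO_MOTION: (),
    MotionClass.FLEXION: (MotionClass.FLEXION,),
    MotionClass.EXTENSION: (MotionClass.EXTENSION,),
    MotionClass.PRONATION: (MotionClass.PRONATION,),
    MotionClass.SUPINATION: (MotionClass.SUPINATION,),
    MotionClass.EXT_PRO: (MotionClass.EXTENSION, MotionClass.PRONATION),
    MotionClass.EXT_SUP: (MotionClass.EXTENSION, MotionClass.SUPINATION),
    MotionClass.FLX_PRO: (MotionClass.FLEXION, MotionClass.PRONATION),
    MotionClass.FLX_SUP: (MotionClass.FLEXION, MotionClass.SUPINATION),
}
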