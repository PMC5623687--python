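"""Motion-class vocabulary.

Seven classes of wrist/hand motion are used throughout: hand close (HC),
hand open (HO), wrist extension (WE), wrist flexion (WF), wrist pronation
(WP), wrist supination (WS), and the unique rest class no-movement (NM).
Labels are carried as their two-letter codes; :class:`MotionClass` is the
typed vocabulary for API users and validation.
"""

from __future__ import annotations

from enum import Enum


class MotionClass(str, Enum):
    """The seven motion classes; members compare equal to their codes."""

    HC = "HC"
    HO = "HO"
    WE = "WE"
    WF = "WF"
    WP = "WP"
    WS = "WS"
    NM = "NM"


#: Canonical class order used for confusion matrices and tie-breaks.
CLASS_ORDER: tuple[str, ...] = ("HC", "HO", "WE", "WF", "WP", "WS", "NM")

#: The six active (non-rest) classes.
ACTIVE_CLASSES: tuple[str, ...] = ("HC", "HO", "WE", "WF", "WP", "WS")

#: The rest class.
NM: str = "NM"


def as_label(value) -> str:
    """Normalize a class given as a MotionClass or 2-letter code."""
    code = value.value if isinstance(value, MotionClass) else str(value)
    if code not in CLASS_ORDER:
        raise ValueError(f"unknown motion class {value!r}")
    return code
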