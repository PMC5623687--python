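"""Online performance metrics against a designated prompt sequence.

Every analysis window of the online task carries a designated class (the
prompt the subject follows). Any per-window deviation of the evaluated
output from the prompt counts as an error — including response-delay
mismatch, deliberately, so the metrics reflect whole-system online
performance rather than classifier accuracy alone.

Overall metrics:

* **TER** — errors over the whole task / total windows;
* **MER** — errors during designated motion / motion windows;
* **RER** — errors during designated rest / rest windows.

The error counts satisfy ``TER * L = MER * L_motion + RER * L_rest``
exactly.

Motion-specific metrics, per designated class over all of its spans:

* **MSTER** — any error within the class's windows;
* **MSAER** — active errors only (output is a wrong non-NM class);
* **MSSR** — switches: entries into a (new) wrong active class, counted
  once at the window where the wrong class first appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .features import WindowSpec, segment
from .motions import ACTIVE_CLASSES, NM, as_label
from .signals import SignalRecording


def designated_from_recording(
    recording: SignalRecording, spec: WindowSpec | None = None
) -> np.ndarray:
    """Per-window designated sequence implied by the ground-truth labels."""
    return segment(recording, spec).labels.copy()


def _as_seq(x) -> np.ndarray:
    return np.array([as_label(c) for c in x], dtype="<U2")


@dataclass
class OverallMetrics:
    ter: float
    mer: float
    rer: float
    total_errors: int
    motion_errors: int
    rest_errors: int
    n_total: int
    n_motion: int
    n_rest: int


@dataclass
class MotionSpecificMetrics:
    mster: float
    msaer: float
    mssr: float
    errors: int
    active_errors: int
    switches: int
    span_length: int


@dataclass
class MetricReport:
    """All six online metrics plus raw counts."""

    overall: OverallMetrics
    per_class: dict[str, MotionSpecificMetrics]

    def to_text(self) -> str:
        o = self.overall
        lines = [
            f"TER {100 * o.ter:6.2f}%  ({o.total_errors}/{o.n_total})",
            f"MER {100 * o.mer:6.2f}%  ({o.motion_errors}/{o.n_motion})",
            f"RER {100 * o.rer:6.2f}%  ({o.rest_errors}/{o.n_rest})",
            "class  MSTER%  MSAER%   MSSR%  windows",
        ]
        for cls, m in self.per_class.items():
            lines.append(
                f"{cls:>5} {100 * m.mster:7.2f} {100 * m.msaer:7.2f}"
                f" {100 * m.mssr:7.2f} {m.span_length:8d}"
            )
        return "\n".join(lines)


def overall_metrics(designated, actual) -> OverallMetrics:
    """TER, MER and RER of an output sequence against the prompt."""
    des, act = _as_seq(designated), _as_seq(actual)
    if des.shape != act.shape:
        raise InvalidInputError("designated and actual sequences differ in length")
    err = des != act
    motion = des != NM
    n = des.size
    n_motion = int(motion.sum())
    n_rest = n - n_motion
    e_motion = int(np.count_nonzero(err & motion))
    e_rest = int(np.count_nonzero(err & ~motion))
    return OverallMetrics(
        ter=(e_motion + e_rest) / n if n else 0.0,
        mer=e_motion / n_motion if n_motion else 0.0,
        rer=e_rest / n_rest if n_rest else 0.0,
        total_errors=e_motion + e_rest,
        motion_errors=e_motion,
        rest_errors=e_rest,
        n_total=n,
        n_motion=n_motion,
        n_rest=n_rest,
    )


def count_switches(designated, actual) -> int:
    """Entries into a wrong active class within designated-motion windows.

    A switch is counted at each window where the output is active, differs
    from the designated class, and differs from the previous window's
    output; consecutive identical wrong windows count once.
    """
    des, act = _as_seq(designated), _as_seq(actual)
    switches = 0
    for i in range(des.size):
        if des[i] == NM:
            continue
        if act[i] == NM or act[i] == des[i]:
            continue
        prev = act[i - 1] if i else None
        if act[i] != prev:
            switches += 1
    return switches


def motion_specific_metrics(
    designated, actual
) -> dict[str, MotionSpecificMetrics]:
    """Per-class MSTER, MSAER and MSSR over the class's designated spans.

    Classes absent from the designated sequence are omitted (their metrics
    are undefined).
    """
    des, act = _as_seq(designated), _as_seq(actual)
    if des.shape != act.shape:
        raise InvalidInputError("designated and actual sequences differ in length")
    out: dict[str, MotionSpecificMetrics] = {}
    for cls in ACTIVE_CLASSES:
        sel = des == cls
        length = int(sel.sum())
        if length == 0:
            continue
        errors = int(np.count_nonzero(sel & (act != cls)))
        active_err = int(np.count_nonzero(sel & (act != cls) & (act != NM)))
        switches = 0
        for i in np.flatnonzero(sel):
            if act[i] == NM or act[i] == cls:
                continue
            prev = act[i - 1] if i else None
            if act[i] != prev:
                switches += 1
        out[cls] = MotionSpecificMetrics(
            mster=errors / length,
            msaer=active_err / length,
            mssr=switches / length,
            errors=errors,
            active_errors=active_err,
            switches=switches,
            span_length=length,
        )
    return out


def evaluate(designated, actual) -> MetricReport:
    """Full metric report (overall + motion-specific) for one output."""
    return MetricReport(
        overall=overall_metrics(designated, actual),
        per_class=motion_specific_metrics(designated, actual),
    )
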