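"""Output-locking postprocessor and the 3-point majority-vote baseline.

The locking strategy stabilizes a pattern-recognition output stream during
constant muscle contraction. A per-window motion-onset detector (extMAV,
extTKE or extMMG) is compared against calibrated thresholds and drives a
six-state machine:

1. **Rest** — detector below the onset threshold: emit NM.
2. **Decision** — detector above onset: the classifier output (OCO) passes
   through verbatim while the first six *active* (non-NM) outputs
   accumulate; their majority class becomes the *decision output*.
3. **Rest (abort)** — the detector fell below onset before six active
   windows accrued: emit NM and return to rest.
4. **Locking** — emit the decision output every window, regardless of the
   OCO, until the detector drops below the offset threshold. Occasional
   misclassifications during the contraction are thereby blocked.
5. **Unlocking** (hysteretic detectors only, offset > onset) — the
   detector sits between onset and offset: emit NM. If it climbs back
   above the offset within a short grace period the lock resumes with the
   same decision; a longer excursion forces a fresh decision.
6. **Rest (release)** — detector below onset: the lock and its per-class
   offset are cleared, and a minimal rest duration is required before the
   next decision stage may begin.

For MAV and TKE the offset equals the onset, so state 5 is unreachable and
the machine degenerates to five states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detectors import DetectorSeries, ThresholdSet, ext_mav, ext_mmg, ext_tke
from .errors import InvalidConfigurationError, InvalidInputError, InvalidParameterError
from .features import FeatureMatrix, WindowSpec, build_feature_matrix, segment
from .lda import LDAModel, predict_lda
from .motions import NM, as_label

SCENARIOS = ("OCO", "3MV", "MAV", "TKE", "MMG")


@dataclass(frozen=True)
class PostprocConfig:
    """Tunables of the locking state machine (counts of analysis windows)."""

    decision_window: int = 6  # active windows that form the decision
    unlock_grace: int = 3  # state-5 windows before the decision is remade
    min_rest_windows: int = 3  # consecutive rest windows required after release

    def __post_init__(self) -> None:
        if min(self.decision_window, self.unlock_grace, self.min_rest_windows) < 1:
            raise InvalidParameterError("all state-machine counts must be >= 1")


@dataclass
class StateTrace:
    """Per-window record of the state machine's path.

    ``states[i]`` is the state (1..6) that emitted window ``i``;
    ``emitted[i]`` the motion class sent to the controller; ``decision[i]``
    the decision output in force (empty string outside the lock).
    """

    states: np.ndarray
    emitted: np.ndarray
    decision: np.ndarray

    def locked_runs(self) -> list[tuple[int, int, str]]:
        """Maximal state-4 runs as (start, stop, decision class)."""
        runs = []
        in_run = False
        start = 0
        for i, s in enumerate(self.states):
            if s == 4 and not in_run:
                in_run, start = True, i
            elif s != 4 and in_run:
                runs.append((start, i, str(self.decision[start])))
                in_run = False
        if in_run:
            runs.append((start, len(self.states), str(self.decision[start])))
        return runs


def majority_vote_3(oco) -> np.ndarray:
    """3-point majority vote over the trailing three outputs.

    Window ``i`` emits the mode of the OCO over ``{i-2, i-1, i}``; the
    first two windows pass through; when all three candidates differ the
    previously emitted output is retained. Two consecutive identical
    misclassifications survive the vote — the known weakness this
    package's locking strategy addresses.
    """
    seq = np.array([as_label(c) for c in oco], dtype="<U2")
    if seq.size == 0:
        raise InvalidInputError("empty output sequence")
    out = seq.copy()
    for i in range(2, seq.size):
        a, b, c = seq[i - 2], seq[i - 1], seq[i]
        if a == b or a == c:
            out[i] = a
        elif b == c:
            out[i] = b
        else:  # three distinct candidates
            out[i] = out[i - 1]
    return out


def _majority_most_recent(classes: list[str]) -> str:
    """Majority class; ties go to the class seen most recently."""
    counts: dict[str, int] = {}
    last: dict[str, int] = {}
    for i, c in enumerate(classes):
        counts[c] = counts.get(c, 0) + 1
        last[c] = i
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    return max(tied, key=lambda c: last[c])


def run_locking_postprocessor(
    detector: DetectorSeries,
    oco,
    thresholds: ThresholdSet,
    config: PostprocConfig | None = None,
) -> tuple[np.ndarray, StateTrace]:
    """Apply the six-state locking machine to a (detector, OCO) stream.

    Returns the emitted output sequence and the full state trace. The
    detector series, OCO sequence and thresholds must refer to the same
    detector kind and window alignment.
    """
    config = config or PostprocConfig()
    seq = np.array([as_label(c) for c in oco], dtype="<U2")
    d = detector.values
    if seq.shape != d.shape:
        raise InvalidInputError("detector and OCO sequences differ in length")
    if thresholds.kind != detector.kind:
        raise InvalidInputError(
            f"threshold kind {thresholds.kind} does not match detector {detector.kind}"
        )
    onset = thresholds.onset
    n = seq.size
    states = np.zeros(n, dtype=int)
    emitted = np.empty(n, dtype="<U2")
    decision_col = np.full(n, "", dtype="<U2")

    state = 1
    active: list[str] = []
    decision = ""
    grace = 0
    rest_run = 0

    for i in range(n):
        di, ci = d[i], seq[i]
        while True:  # at most one re-dispatch per window
            if state == 1:
                if di >= onset:
                    state, active = 2, []
                    continue
                states[i], emitted[i] = 1, NM
            elif state == 2:
                if di < onset:
                    states[i], emitted[i] = 3, NM
                    state = 1
                else:
                    states[i], emitted[i] = 2, ci
                    if ci != NM:
                        active.append(ci)
                        if len(active) >= config.decision_window:
                            decision = _majority_most_recent(active)
                            state = 4
            elif state == 4:
                off = thresholds.offset_for(decision)
                if di >= off:
                    states[i], emitted[i] = 4, decision
                    decision_col[i] = decision
                elif di >= onset:  # between onset and offset: unlocking
                    state, grace = 5, 1
                    states[i], emitted[i] = 5, NM
                else:
                    state, rest_run = 6, 1
                    states[i], emitted[i] = 6, NM
                    if rest_run >= config.min_rest_windows:
                        state = 1
            elif state == 5:
                off = thresholds.offset_for(decision)
                if di < onset:
                    state, rest_run = 6, 1
                    states[i], emitted[i] = 6, NM
                    if rest_run >= config.min_rest_windows:
                        state = 1
                elif grace >= config.unlock_grace:
                    # grace exhausted: the decision must be remade
                    state, active = 2, []
                    continue
                elif di >= off:
                    state = 4
                    states[i], emitted[i] = 4, decision
                    decision_col[i] = decision
                else:
                    grace += 1
                    states[i], emitted[i] = 5, NM
            else:  # state 6: enforced rest after a contraction
                if di < onset:
                    rest_run += 1
                    states[i], emitted[i] = 6, NM
                    if rest_run >= config.min_rest_windows:
                        state = 1
                else:
                    rest_run = 0
                    states[i], emitted[i] = 6, NM
            break

    return emitted, StateTrace(states=states, emitted=emitted, decision=decision_col)


def run_scenario(
    recording,
    model: LDAModel | None,
    thresholds: ThresholdSet | None,
    scenario: str,
    window_spec: WindowSpec | None = None,
    deadband: float = 0.0,
    config: PostprocConfig | None = None,
    oco: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, StateTrace | None, np.ndarray]:
    """End-to-end per-window outputs for one processing scenario.

    ``scenario`` is one of OCO (classifier output passed through), 3MV
    (3-point majority vote) or MAV/TKE/MMG (the locking strategy driven by
    that detector). A precomputed ``oco`` stream (e.g. a deliberately
    corrupted one) may be supplied; otherwise the classifier prediction on
    the recording is used.

    Returns ``(output, oco, trace, detector_values)``; the detector values
    of every window are recorded for threshold-sensitivity reconstruction
    (all-zero for OCO/3MV, which use no detector).
    """
    if scenario not in SCENARIOS:
        raise InvalidConfigurationError(f"unknown scenario {scenario!r}")
    window_spec = window_spec or WindowSpec()
    windows = segment(recording, window_spec)
    fm: FeatureMatrix | None = None
    if oco is None:
        if model is None:
            raise InvalidConfigurationError("a model is required to compute the OCO")
        fm = build_feature_matrix(recording, window_spec, deadband)
        oco = predict_lda(model, fm)
    else:
        oco = np.array([as_label(c) for c in oco], dtype="<U2")
        if oco.size != windows.n_windows:
            raise InvalidInputError("supplied OCO does not match the window count")

    if scenario == "OCO":
        return oco.copy(), oco, None, np.zeros(oco.size)
    if scenario == "3MV":
        return majority_vote_3(oco), oco, None, np.zeros(oco.size)

    if thresholds is None:
        raise InvalidConfigurationError(
            f"scenario {scenario} requires calibrated thresholds"
        )
    if scenario == "MAV":
        if fm is None:
            fm = build_feature_matrix(recording, window_spec, deadband)
        detector = ext_mav(fm)
    elif scenario == "TKE":
        detector = ext_tke(recording, windows)
    else:
        detector = ext_mmg(recording, windows)
    output, trace = run_locking_postprocessor(detector, oco, thresholds, config)
    return output, oco, trace, detector.values
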