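"""Threshold-sensitivity reconstruction.

The per-window detector values and classifier outputs recorded during an
online session suffice to replay the locking postprocessor under any
rescaled threshold: no signal reprocessing is needed. Sweeping a grid of
onset-threshold multipliers and replaying yields motion-error and
rest-error curves that characterize how robust a detector is to threshold
choice.

For the EMG-derived detectors (MAV, TKE) onset and offset are defined
equal, so both scale together over a wide grid (0.1x to 10x by default).
For MMG only the onset scales (0.5x to 2x); the per-class offsets stay at
their calibrated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectors import DetectorSeries, ThresholdSet
from .errors import InvalidParameterError
from .metrics import overall_metrics
from .postprocess import PostprocConfig, run_locking_postprocessor

OFFSET_POLICIES = ("scale_with_onset", "fixed")


def default_multipliers(kind: str) -> np.ndarray:
    """Default sweep grids: 25 log-spaced points over [0.1, 10] for the
    EMG-derived detectors, 13 linear points over [0.5, 2] for MMG."""
    if kind == "MMG":
        return np.linspace(0.5, 2.0, 13)
    return np.logspace(-1.0, 1.0, 25)


@dataclass
class SweepSpec:
    """Which detector to sweep, over which multipliers, scaling what."""

    kind: str
    multipliers: np.ndarray | None = None
    offset_policy: str | None = None

    def __post_init__(self) -> None:
        if self.multipliers is None:
            self.multipliers = default_multipliers(self.kind)
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if np.any(self.multipliers <= 0):
            raise InvalidParameterError("threshold multipliers must be positive")
        if np.any(np.diff(self.multipliers) < 0):
            raise InvalidParameterError("multipliers must be sorted ascending")
        if self.offset_policy is None:
            self.offset_policy = "fixed" if self.kind == "MMG" else "scale_with_onset"
        if self.offset_policy not in OFFSET_POLICIES:
            raise InvalidParameterError(
                f"offset_policy must be one of {OFFSET_POLICIES}"
            )


@dataclass
class SweepResult:
    """Per-multiplier motion/rest error fractions and raw counts."""

    kind: str
    multipliers: np.ndarray
    motion_error: np.ndarray
    rest_error: np.ndarray
    motion_error_count: np.ndarray = field(default=None)
    rest_error_count: np.ndarray = field(default=None)

    def as_rows(self) -> list[dict]:
        return [
            {
                "multiplier": float(m),
                "motion_error": float(me),
                "rest_error": float(re),
                "motion_error_count": int(mec),
                "rest_error_count": int(rec),
            }
            for m, me, re, mec, rec in zip(
                self.multipliers, self.motion_error, self.rest_error,
                self.motion_error_count, self.rest_error_count,
            )
        ]


def sweep(
    detector_values: np.ndarray,
    oco,
    base_thresholds: ThresholdSet,
    designated,
    spec: SweepSpec | None = None,
    config: PostprocConfig | None = None,
) -> SweepResult:
    """Replay the locking postprocessor over a grid of threshold multipliers.

    Each multiplier reruns the full state machine on the recorded
    (detector, OCO) stream with the onset threshold scaled — and, per the
    offset policy, the offsets too — then scores MER and RER against the
    designated sequence. Replaying at multiplier 1.0 reproduces the
    original run exactly.
    """
    spec = spec or SweepSpec(kind=base_thresholds.kind)
    if spec.kind != base_thresholds.kind:
        raise InvalidParameterError("sweep kind does not match the thresholds")
    scale_offset = spec.offset_policy == "scale_with_onset"
    motion_err, rest_err = [], []
    motion_cnt, rest_cnt = [], []
    for m in spec.multipliers:
        scaled = base_thresholds.scaled(float(m), scale_offset=scale_offset)
        series = DetectorSeries(kind=scaled.kind, values=np.asarray(detector_values))
        output, _ = run_locking_postprocessor(series, oco, scaled, config)
        o = overall_metrics(designated, output)
        motion_err.append(o.mer)
        rest_err.append(o.rer)
        motion_cnt.append(o.motion_errors)
        rest_cnt.append(o.rest_errors)
    return SweepResult(
        kind=spec.kind,
        multipliers=spec.multipliers.copy(),
        motion_error=np.array(motion_err),
        rest_error=np.array(rest_err),
        motion_error_count=np.array(motion_cnt, dtype=int),
        rest_error_count=np.array(rest_cnt, dtype=int),
    )
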