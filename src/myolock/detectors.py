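"""Motion-onset detectors and their threshold calibration.

Three per-window scalar detectors drive the locking postprocessor:

* **extMAV** — the six channel MAV features summed per window;
* **extTKE** — the Teager–Kaiser energy operator
  ``x(k)^2 - x(k-1) x(k+1)`` computed per EMG sample (interior points
  only), summed across channels, then the per-window maximum;
* **extMMG** — the per-window maximum of the raw MMG signal.

EMG-derived detectors (MAV, TKE) use a single threshold for onset and
offset: baseline mean plus three standard deviations over rest windows.
The MMG detector is hysteretic: the onset threshold is one third of the
smallest initial peaking value (IPV) over all training contractions, and
each motion class's offset threshold is two thirds of that class's
smallest plateau amplitude — offsets sit above the onset, which creates
the unlocking stage of the state machine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CalibrationWarning,
    IncompleteCalibrationError,
    InsufficientBaselineError,
    InvalidInputError,
)
from .features import FeatureMatrix, WindowSeries
from .motions import ACTIVE_CLASSES, NM
from .signals import SignalRecording

DETECTOR_KINDS = ("MAV", "TKE", "MMG")


@dataclass
class DetectorSeries:
    """One detector scalar per analysis window."""

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in DETECTOR_KINDS:
            raise InvalidInputError(f"unknown detector kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or not np.all(np.isfinite(self.values)):
            raise InvalidInputError("detector values must be a finite 1-D series")


@dataclass
class BaselineStats:
    """Mean and SD of a detector over rest windows (population SD)."""

    mean: float
    sd: float
    n_windows: int


@dataclass
class ThresholdSet:
    """Onset/offset thresholds of one detector.

    MAV and TKE carry a single scalar ``offset`` equal to ``onset``; MMG
    carries a per-class ``offset_map``. ``provenance`` records the
    calibration inputs (baseline statistics, or the IPV and plateau values
    per class and trial).
    """

    kind: str
    onset: float
    offset: float | None = None
    offset_map: dict[str, float] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DETECTOR_KINDS:
            raise InvalidInputError(f"unknown detector kind {self.kind!r}")
        if not self.onset > 0:
            raise InvalidInputError("onset threshold must be positive")
        if self.offset is None and self.offset_map is None:
            raise InvalidInputError("a threshold set needs an offset")
        if self.offset_map is not None:
            low = [c for c, v in self.offset_map.items() if v < self.onset]
            if low:
                warnings.warn(
                    f"offset threshold below onset for classes {sorted(low)}",
                    CalibrationWarning,
                    stacklevel=2,
                )

    def offset_for(self, cls: str) -> float:
        if self.offset_map is not None:
            if cls not in self.offset_map:
                raise IncompleteCalibrationError(
                    f"no offset threshold calibrated for class {cls}"
                )
            return self.offset_map[cls]
        assert self.offset is not None
        return self.offset

    def scaled(self, multiplier: float, scale_offset: bool) -> "ThresholdSet":
        """Rescaled copy: onset always, offsets only when requested."""
        if not multiplier > 0:
            raise InvalidInputError("threshold multiplier must be positive")
        offset = self.offset
        offset_map = self.offset_map
        if scale_offset:
            offset = None if offset is None else offset * multiplier
            offset_map = (
                None
                if offset_map is None
                else {c: v * multiplier for c, v in offset_map.items()}
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CalibrationWarning)
            return ThresholdSet(
                kind=self.kind, onset=self.onset * multiplier,
                offset=offset, offset_map=offset_map,
                provenance=dict(self.provenance, scaled_by=multiplier),
            )


def ext_mav(feature_matrix: FeatureMatrix) -> DetectorSeries:
    """Per-window sum of the six channel MAV features."""
    idx = feature_matrix.column_indices("mav")
    return DetectorSeries("MAV", feature_matrix.values[:, idx].sum(axis=1))


def tke_pointwise(x) -> np.ndarray:
    """Teager–Kaiser energy at every interior sample of one channel.

    For ``x(k) = A cos(w k + phi)`` this is the constant ``A^2 sin^2 w``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidInputError("TKE needs at least 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def ext_tke(recording: SignalRecording, windows: WindowSeries) -> DetectorSeries:
    """Per-window maximum of the channel-summed pointwise TKE.

    The first and last sample of each window carry no TKE value; the
    maximum runs over the window's interior points.
    """
    if recording.n_channels < 1:
        raise InvalidInputError("no EMG channels")
    # TKE at global interior sample k (1..N-2) equals the window-local
    # value whenever k-1, k, k+1 all lie inside the window.
    summed = np.zeros(recording.n_samples)
    for ch in range(recording.n_channels):
        summed[1:-1] += tke_pointwise(recording.emg[ch])
    values = np.array(
        [summed[a + 1 : b - 1].max() for a, b in windows.bounds()]
    ) if windows.n_windows else np.empty(0)
    return DetectorSeries("TKE", values)


def ext_mmg(recording: SignalRecording, windows: WindowSeries) -> DetectorSeries:
    """Per-window maximum of the raw MMG samples."""
    if recording.mmg.size != recording.n_samples:
        raise InvalidInputError("MMG channel missing or misaligned")
    values = np.array(
        [recording.mmg[a:b].max() for a, b in windows.bounds()]
    ) if windows.n_windows else np.empty(0)
    return DetectorSeries("MMG", values)


def baseline_window_mask(
    recording: SignalRecording,
    windows: WindowSeries,
    guard_ms: float = 300.0,
) -> np.ndarray:
    """Rest windows usable as baseline.

    A window qualifies when all of its samples are rest (NM) and its start
    lies at least ``guard_ms`` after the most recent active sample, so the
    decaying tail of a contraction never contaminates the baseline.
    """
    fs = recording.sampling_rate
    guard = int(round(guard_ms * fs / 1000.0))
    active = recording.labels != NM
    # index of the most recent active sample at or before each position
    last_active = np.where(active, np.arange(recording.n_samples), -1)
    last_active = np.maximum.accumulate(last_active)
    any_active = np.cumsum(active)
    mask = np.zeros(windows.n_windows, dtype=bool)
    for i, (a, b) in enumerate(windows.bounds()):
        all_rest = (any_active[b - 1] - (any_active[a - 1] if a else 0)) == 0
        quiet = last_active[a] < 0 or (a - last_active[a]) >= guard
        mask[i] = all_rest and quiet
    return mask


def baseline_stats(values: np.ndarray, ddof: int = 0) -> BaselineStats:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientBaselineError("need at least 2 baseline windows")
    return BaselineStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=ddof)),
        n_windows=int(values.size),
    )


def calibrate_emg_threshold(
    baseline: DetectorSeries | np.ndarray,
    kind: str | None = None,
    n_sd: float = 3.0,
    ddof: int = 0,
) -> ThresholdSet:
    """Single onset=offset threshold: baseline mean + 3 SD.

    ``ddof=0`` (population SD) is the default convention; pass ``ddof=1``
    for the sample SD.
    """
    if isinstance(baseline, DetectorSeries):
        kind = kind or baseline.kind
        values = baseline.values
    else:
        if kind is None:
            raise InvalidInputError("kind is required for a bare value array")
        values = np.asarray(baseline, dtype=float)
    stats = baseline_stats(values, ddof=ddof)
    threshold = stats.mean + n_sd * stats.sd
    return ThresholdSet(
        kind=kind, onset=threshold, offset=threshold,
        provenance={
            "baseline_mean": stats.mean,
            "baseline_sd": stats.sd,
            "n_windows": stats.n_windows,
            "n_sd": n_sd,
            "ddof": ddof,
        },
    )


def check_emg_calibration(
    thresholds: ThresholdSet, active_values: np.ndarray, percentile: float = 5.0
) -> bool:
    """Warn when a threshold is unusable (rest baseline reaches activity).

    Mirrors the field observation that EMG-derived detectors sometimes
    cannot be thresholded for a subject: if the onset threshold exceeds
    the 5th percentile of active-window detector values, contractions
    would frequently fail to trigger. Returns True when calibration looks
    usable.
    """
    active_values = np.asarray(active_values, dtype=float)
    if active_values.size == 0:
        return True
    floor = float(np.percentile(active_values, percentile))
    if thresholds.onset > floor:
        warnings.warn(
            f"{thresholds.kind} onset threshold {thresholds.onset:.4g} exceeds "
            f"the {percentile:g}th percentile of active windows ({floor:.4g}); "
            "threshold may be undeterminable for this recording",
            CalibrationWarning,
            stacklevel=2,
        )
        return False
    return True


def estimate_ipv(
    mmg_trace: np.ndarray,
    onset_index: int,
    sampling_rate: float,
    span_ms: float = 500.0,
) -> float:
    """Initial peaking value: max MMG within a span after contraction onset."""
    mmg_trace = np.asarray(mmg_trace, dtype=float)
    if not 0 <= onset_index < mmg_trace.size:
        raise InvalidInputError("onset_index outside the trace")
    span = int(round(span_ms * sampling_rate / 1000.0))
    region = mmg_trace[onset_index : onset_index + max(span, 1)]
    if region.size == 0:
        raise InvalidInputError("empty initial-peak search span")
    ipv = float(region.max())
    if ipv <= 0:
        warnings.warn(
            "degenerate IPV calibration: no positive MMG in the onset region",
            CalibrationWarning,
            stacklevel=2,
        )
    return ipv


def estimate_plateau(mmg_trace: np.ndarray, span: tuple[int, int]) -> float:
    """Plateau amplitude: median MMG over the middle 50% of a contraction."""
    mmg_trace = np.asarray(mmg_trace, dtype=float)
    a, b = span
    if not (0 <= a < b <= mmg_trace.size) or (b - a) < 4:
        raise InvalidInputError("contraction span too short for a plateau estimate")
    q = (b - a) // 4
    return float(np.median(mmg_trace[a + q : b - q]))


def calibrate_mmg_thresholds(
    recording: SignalRecording,
    ipv_span_ms: float = 500.0,
    required_classes: tuple[str, ...] = ACTIVE_CLASSES,
) -> ThresholdSet:
    """Calibrate the MMG onset and per-class offset thresholds.

    Every contraction run in the training recording contributes one IPV
    and one plateau estimate, keyed by (class, trial). The onset threshold
    is one third of the global IPV minimum; each class's offset threshold
    is two thirds of its plateau minimum.
    """
    runs = recording.active_runs()
    ipv: dict[str, list[float]] = {}
    plateau: dict[str, list[float]] = {}
    for cls, a, b in runs:
        ipv.setdefault(cls, []).append(
            estimate_ipv(recording.mmg, a, recording.sampling_rate, ipv_span_ms)
        )
        plateau.setdefault(cls, []).append(estimate_plateau(recording.mmg, (a, b)))
    missing = [c for c in required_classes if c not in ipv]
    if missing:
        raise IncompleteCalibrationError(
            f"no contraction trials for classes {missing}"
        )
    all_ipv = [v for vs in ipv.values() for v in vs]
    onset = min(all_ipv) / 3.0
    offset_map = {c: 2.0 / 3.0 * min(plateau[c]) for c in plateau}
    return ThresholdSet(
        kind="MMG", onset=onset, offset_map=offset_map,
        provenance={"ipv": ipv, "plateau": plateau},
    )
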