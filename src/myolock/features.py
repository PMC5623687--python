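"""Sliding-window segmentation and Hudgins time-domain features.

The signal is cut into overlapping analysis windows (150 ms length,
100 ms increment by default, i.e. 50 ms overlap), and four time-domain
features are computed per window and EMG channel:

* **MAV** — mean absolute value, ``mean(|x|)``;
* **ZC** — number of zero crossings whose amplitude step exceeds a
  deadband;
* **WL** — waveform length, ``sum(|diff(x)|)``;
* **SSC** — slope sign changes whose adjacent slopes both exceed the
  deadband in magnitude.

Stacked channel-major (ch1 MAV, ZC, WL, SSC, ch2 ...), six channels give
the classifier's 24-column feature matrix. The deadband defaults to 0; a
positive value suppresses noise-driven ZC/SSC counts.

Windows are labeled by their **last** sample's ground truth — the causal
convention, since an online decision can only use past samples. With a
16,000-sample single-class signal at 1 kHz, the default windowing yields
``floor((16000 - 150)/100) + 1 = 159`` windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidConfigurationError, InvalidInputError, InvalidParameterError
from .motions import CLASS_ORDER
from .signals import SignalRecording

FEATURE_NAMES: tuple[str, ...] = ("mav", "zc", "wl", "ssc")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds."""

    length_ms: float = 150.0
    increment_ms: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.increment_ms <= self.length_ms:
            raise InvalidParameterError("require 0 < increment_ms <= length_ms")

    def in_samples(self, sampling_rate: float) -> tuple[int, int]:
        """(window length, increment) in samples at ``sampling_rate``."""
        w = int(round(self.length_ms * sampling_rate / 1000.0))
        i = int(round(self.increment_ms * sampling_rate / 1000.0))
        return w, i


@dataclass
class WindowSeries:
    """Equal-length windows advancing by a fixed increment.

    ``starts[k]`` is the first sample of window ``k``; windows are the
    half-open ranges ``[start, start + length)``.
    """

    starts: np.ndarray
    length: int
    increment: int
    labels: np.ndarray
    source_rate: float

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def bounds(self) -> list[tuple[int, int]]:
        return [(int(s), int(s) + self.length) for s in self.starts]


def window_count(n_samples: int, length: int, increment: int) -> int:
    """Number of full windows: ``floor((N - W) / I) + 1`` (0 if N < W)."""
    if n_samples < length:
        return 0
    return (n_samples - length) // increment + 1


def segment(recording: SignalRecording, spec: WindowSpec | None = None) -> WindowSeries:
    """Cut a recording into sliding analysis windows.

    A recording shorter than one window yields an empty series (this is a
    documented degenerate case, not an error). Window labels follow the
    causal last-sample rule.
    """
    spec = spec or WindowSpec()
    w, inc = spec.in_samples(recording.sampling_rate)
    n = window_count(recording.n_samples, w, inc)
    starts = np.arange(n) * inc
    labels = (
        recording.labels[starts + w - 1] if n else np.empty(0, dtype="<U2")
    )
    return WindowSeries(
        starts=starts, length=w, increment=inc, labels=labels,
        source_rate=recording.sampling_rate,
    )


def feature_mav(x) -> float:
    """Mean absolute value of a window."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("MAV of an empty window")
    return float(np.mean(np.abs(x)))


def feature_zc(x, deadband: float = 0.0) -> int:
    """Zero crossings with an amplitude-step deadband."""
    if deadband < 0:
        raise InvalidParameterError("deadband must be >= 0")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0
    sign_change = x[:-1] * x[1:] < 0
    step = np.abs(np.diff(x)) > deadband
    return int(np.count_nonzero(sign_change & step))


def feature_wl(x) -> float:
    """Waveform length: total absolute first difference."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidInputError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def feature_ssc(x, deadband: float = 0.0) -> int:
    """Slope sign changes with a slope-magnitude deadband."""
    if deadband < 0:
        raise InvalidParameterError("deadband must be >= 0")
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidInputError("slope sign changes need at least 3 samples")
    d = np.diff(x)
    s1, s2 = d[:-1], d[1:]
    flips = (s1 * s2 < 0) & (np.abs(s1) > deadband) & (np.abs(s2) > deadband)
    return int(np.count_nonzero(flips))


@dataclass
class FeatureMatrix:
    """Per-window stacked features with aligned class labels.

    ``values`` is windows x (channels * 4) in channel-major order
    (ch1 mav, zc, wl, ssc, ch2 mav, ...); ``columns`` names every column.
    """

    values: np.ndarray
    labels: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U2")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise InvalidInputError("feature values do not match the column names")
        if self.values.shape[0] != self.labels.shape[0]:
            raise InvalidInputError("one label per feature row is required")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def column_indices(self, feature: str) -> list[int]:
        """Indices of one feature's columns across channels, channel order."""
        if feature not in FEATURE_NAMES:
            raise InvalidInputError(f"unknown feature {feature!r}")
        idx = [i for i, c in enumerate(self.columns) if c.endswith(f"_{feature}")]
        if not idx:
            raise InvalidInputError(f"no {feature!r} columns present")
        return idx


def default_columns(n_channels: int = 6) -> tuple[str, ...]:
    return tuple(
        f"ch{ch + 1}_{f}" for ch in range(n_channels) for f in FEATURE_NAMES
    )


def _window_features(sig: np.ndarray, windows: WindowSeries, deadband: float) -> np.ndarray:
    """All four features of one channel for every window, vectorized."""
    if windows.n_windows == 0:
        return np.empty((0, 4))
    view = sliding_window_view(sig, windows.length)[:: windows.increment]
    view = view[: windows.n_windows]
    mav = np.mean(np.abs(view), axis=1)
    d = np.diff(view, axis=1)
    wl = np.sum(np.abs(d), axis=1)
    zc = np.count_nonzero(
        (view[:, :-1] * view[:, 1:] < 0) & (np.abs(d) > deadband), axis=1
    )
    flips = (d[:, :-1] * d[:, 1:] < 0) & (np.abs(d[:, :-1]) > deadband) & (
        np.abs(d[:, 1:]) > deadband
    )
    ssc = np.count_nonzero(flips, axis=1)
    return np.column_stack([mav, zc, wl, ssc])


def build_feature_matrix(
    recording: SignalRecording,
    spec: WindowSpec | None = None,
    deadband: float = 0.0,
    n_channels: int = 6,
) -> FeatureMatrix:
    """Feature matrix of a continuous recording (all windows, all channels)."""
    if deadband < 0:
        raise InvalidParameterError("deadband must be >= 0")
    if recording.n_channels != n_channels:
        raise InvalidConfigurationError(
            f"expected {n_channels} EMG channels, got {recording.n_channels}"
        )
    windows = segment(recording, spec)
    blocks = [
        _window_features(recording.emg[ch], windows, deadband)
        for ch in range(recording.n_channels)
    ]
    values = (
        np.hstack(blocks) if windows.n_windows else np.empty((0, 4 * n_channels))
    )
    return FeatureMatrix(
        values=values, labels=windows.labels.copy(),
        columns=default_columns(recording.n_channels),
    )


def per_class_feature_matrix(
    recording: SignalRecording,
    spec: WindowSpec | None = None,
    deadband: float = 0.0,
    equalize: bool = True,
) -> FeatureMatrix:
    """Offline-style feature matrix: segment each class's signal separately.

    All of a class's contraction runs are concatenated (in recording
    order) and segmented as one signal, mirroring per-class offline
    acquisition; with ``equalize`` every class is truncated to the
    shortest class's total length, balancing window counts (the rest
    class accrues far more raw signal than any motion).
    """
    spec = spec or WindowSpec()
    per_class: dict[str, list[np.ndarray]] = {}
    for cls, a, b in recording.label_runs():
        per_class.setdefault(cls, []).append(np.arange(a, b))
    if not per_class:
        raise InvalidInputError("empty recording")
    concat = {
        cls: np.concatenate(parts) for cls, parts in per_class.items()
    }
    limit = min(idx.size for idx in concat.values()) if equalize else None
    chunks, labels = [], []
    for cls in CLASS_ORDER:
        if cls not in concat:
            continue
        idx = concat[cls][:limit] if limit else concat[cls]
        sub = SignalRecording(
            emg=recording.emg[:, idx], mmg=recording.mmg[idx],
            labels=np.full(idx.size, cls, dtype="<U2"),
            sampling_rate=recording.sampling_rate,
        )
        fm = build_feature_matrix(sub, spec, deadband, recording.n_channels)
        chunks.append(fm.values)
        labels.append(fm.labels)
    return FeatureMatrix(
        values=np.vstack(chunks), labels=np.concatenate(labels),
        columns=default_columns(recording.n_channels),
    )
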