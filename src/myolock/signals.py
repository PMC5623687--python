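"""Synchronized multichannel EMG + MMG recordings.

A :class:`SignalRecording` holds six channels of surface EMG, one
mechanomyogram (force-sensing-resistor) channel, and a ground-truth motion
class for every sample, all at a common sampling rate. Amplitudes are in
arbitrary units; every downstream threshold is calibrated from the data
themselves, so the absolute scale never matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .motions import CLASS_ORDER, NM


@dataclass
class SignalRecording:
    """Six EMG channels, one MMG channel, and per-sample class labels.

    Parameters
    ----------
    emg : ndarray, shape (n_channels, n_samples)
        Surface EMG, arbitrary units.
    mmg : ndarray, shape (n_samples,)
        Mechanomyogram (FSR) signal, arbitrary units.
    labels : ndarray of 2-letter codes, shape (n_samples,)
        Ground-truth motion class of every sample.
    sampling_rate : float
        Samples per second, > 0.
    """

    emg: np.ndarray
    mmg: np.ndarray
    labels: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        if self.emg.ndim != 2:
            raise InvalidInputError("emg must be a 2-D (channels x samples) array")
        self.mmg = np.asarray(self.mmg, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U2")
        n = self.emg.shape[1]
        if self.mmg.shape != (n,) or self.labels.shape != (n,):
            raise InvalidInputError("emg, mmg and labels must cover the same samples")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")
        bad = set(np.unique(self.labels)) - set(CLASS_ORDER)
        if bad:
            raise InvalidInputError(f"unknown labels in recording: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate

    def label_runs(self) -> list[tuple[str, int, int]]:
        """Maximal constant-label runs as (label, start, stop) half-open spans."""
        if self.n_samples == 0:
            return []
        change = np.flatnonzero(self.labels[1:] != self.labels[:-1]) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [self.n_samples]))
        return [(str(self.labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]

    def active_runs(self) -> list[tuple[str, int, int]]:
        """Contraction spans: constant-label runs whose class is not NM."""
        return [r for r in self.label_runs() if r[0] != NM]
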