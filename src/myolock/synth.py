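"""Seeded synthetic EMG + MMG session generator.

The generator emulates the phenomenology a threshold-based onset detector
and an output-locking postprocessor rely on, not motor-unit physiology:

* **EMG** per channel is amplitude-modulated Gaussian noise. A per-class
  six-channel gain pattern defines where each motion "lives" on the
  forearm; a first-order (asymmetric rise/fall) smoothing of the on/off
  gain profile gives the burst envelope; trial-to-trial amplitude jitter
  and a slow within-contraction force modulation give the realistic
  overlap between classes; independent baseline noise is always present.
* **MMG** (force-sensing-resistor signal) is a lagged trapezoidal envelope
  per contraction with a multiplicative overshoot pulse at onset — the
  initial peaking value (IPV) exceeds the later plateau — plus noise.
  The MMG envelope trails the EMG envelope by ``mmg_lag_ms``.

Both the offline training/testing protocol (each motion held 4 s, 3 s rest
between, four repetitions, 1 kHz sampling) and the online task (the
designated WP-WE-HO-WS-HC-WF sequence with ~2 s contractions and ~2 s
rests, four consecutive trials) are available as ready-made protocols.

All randomness flows from one integer seed through one generator consumed
in a fixed, documented order, so identical inputs give bit-identical
recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, InvalidProtocolError
from .motions import ACTIVE_CLASSES, NM, as_label
from .signals import SignalRecording

N_CHANNELS = 6

#: Motion order of the offline acquisition protocol.
OFFLINE_SEQUENCE: tuple[str, ...] = ("HC", "HO", "WE", "WF", "WP", "WS")

#: The designated motion order of the online task.
ONLINE_SEQUENCE: tuple[str, ...] = ("WP", "WE", "HO", "WS", "HC", "WF")


@dataclass
class SessionProtocol:
    """An ordered list of (motion class, duration in seconds) segments."""

    segments: list[tuple[str, float]]
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise InvalidProtocolError("sampling_rate must be positive")
        if not self.segments:
            raise InvalidProtocolError("protocol must contain at least one segment")
        self.segments = [(as_label(c), float(d)) for c, d in self.segments]
        if any(d <= 0 for _, d in self.segments):
            raise InvalidProtocolError("segment durations must be positive")

    def segment_samples(self) -> list[tuple[str, int]]:
        fs = self.sampling_rate
        return [(c, int(round(d * fs))) for c, d in self.segments]

    def labels(self) -> np.ndarray:
        """Per-sample ground-truth labels implied by the protocol."""
        parts = [np.full(n, c, dtype="<U2") for c, n in self.segment_samples()]
        return np.concatenate(parts)

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.segment_samples())


def offline_protocol(
    motion_s: float = 4.0,
    rest_s: float = 3.0,
    repetitions: int = 4,
    sequence: tuple[str, ...] = OFFLINE_SEQUENCE,
    sampling_rate: float = 1000.0,
) -> SessionProtocol:
    """The offline acquisition protocol: 4 s contractions, 3 s rests, 4 reps.

    Each active class accumulates ``motion_s * repetitions`` seconds of
    contraction (16 s by default, i.e. 16,000 samples at 1 kHz).
    """
    segments: list[tuple[str, float]] = [(NM, rest_s)]
    for _ in range(repetitions):
        for cls in sequence:
            segments.append((cls, motion_s))
            segments.append((NM, rest_s))
    return SessionProtocol(segments, sampling_rate)


def online_protocol(
    motion_s: float = 2.0,
    rest_s: float = 2.0,
    trials: int = 4,
    sequence: tuple[str, ...] = ONLINE_SEQUENCE,
    sampling_rate: float = 1000.0,
) -> SessionProtocol:
    """The online task: WP-WE-HO-WS-HC-WF, ~2 s motion / ~2 s rest, 4 trials."""
    segments: list[tuple[str, float]] = [(NM, rest_s)]
    for _ in range(trials):
        for cls in sequence:
            segments.append((cls, motion_s))
            segments.append((NM, rest_s))
    return SessionProtocol(segments, sampling_rate)


def _default_gains() -> dict[str, np.ndarray]:
    """Per-class six-channel EMG gain patterns.

    Each active class has a dominant electrode plus crosstalk onto the next
    electrode around the forearm; neighbouring patterns overlap enough that
    trial-to-trial amplitude variability produces occasional confusions,
    as seen in real offline confusion matrices. Rest has zero gain.
    """
    gains: dict[str, np.ndarray] = {NM: np.zeros(N_CHANNELS)}
    for i, cls in enumerate(ACTIVE_CLASSES):
        g = np.full(N_CHANNELS, 0.15)
        g[i] = 1.0
        g[(i + 1) % N_CHANNELS] = 0.45
        gains[cls] = g
    return gains


def _default_plateaus() -> dict[str, float]:
    # Per-class MMG plateau amplitudes (a.u.); distinct forces per motion.
    return {"HC": 2.2, "HO": 1.8, "WE": 2.0, "WF": 2.4, "WP": 1.7, "WS": 2.1}


@dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic session generator.

    Attributes
    ----------
    channel_gain : per-class 6-vector of EMG amplitude gains (a.u.).
    baseline_sd : EMG rest-noise standard deviation (a.u.).
    envelope_rise_ms, envelope_fall_ms : EMG activation time constants.
    amplitude_jitter_sd : SD of the per-contraction log-amplitude jitter
        (trial-to-trial force variability).
    force_mod_depth, force_mod_freq_hz : slow sinusoidal force modulation
        within a contraction.
    fatigue_drift : fractional EMG amplitude change per second of
        contraction (0 disables it).
    mmg_lag_ms : MMG onset/offset delay relative to EMG.
    mmg_rise_ms, mmg_fall_ms : MMG trapezoid ramp durations.
    mmg_overshoot : ratio of the initial MMG peak to the plateau (>= 1).
    mmg_overshoot_decay_ms : decay constant of the onset overshoot pulse.
    mmg_plateau : per-class plateau amplitude (a.u.).
    mmg_noise_sd : MMG additive noise SD (a.u.).
    seed : integer seed of the single pseudo-random stream.
    """

    channel_gain: dict[str, np.ndarray] = field(default_factory=_default_gains)
    baseline_sd: float = 0.06
    envelope_rise_ms: float = 30.0
    envelope_fall_ms: float = 40.0
    amplitude_jitter_sd: float = 0.35
    force_mod_depth: float = 0.15
    force_mod_freq_hz: float = 0.6
    fatigue_drift: float = 0.0
    mmg_lag_ms: float = 150.0
    mmg_rise_ms: float = 100.0
    mmg_fall_ms: float = 80.0
    mmg_overshoot: float = 1.5
    mmg_overshoot_decay_ms: float = 300.0
    mmg_plateau: dict[str, float] = field(default_factory=_default_plateaus)
    mmg_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.mmg_noise_sd < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")
        if self.amplitude_jitter_sd < 0:
            raise InvalidParameterError("amplitude_jitter_sd must be >= 0")
        if self.mmg_overshoot < 1:
            raise InvalidParameterError("mmg_overshoot must be >= 1")
        self.channel_gain = {
            as_label(c): np.asarray(g, dtype=float) for c, g in self.channel_gain.items()
        }
        for c, g in self.channel_gain.items():
            if g.shape != (N_CHANNELS,) or np.any(g < 0):
                raise InvalidParameterError(
                    f"channel_gain[{c}] must be 6 nonnegative values"
                )

    def replace(self, **kwargs) -> "GeneratorParams":
        return dataclasses.replace(self, **kwargs)


def separable_params(seed: int = 0) -> GeneratorParams:
    """A high-SNR configuration with orthogonal class gain patterns.

    One dominant electrode per class, no crosstalk, small baseline noise
    and no trial-to-trial variability: classes are separable by
    construction, which is useful for classifier sanity checks.
    """
    gains: dict[str, np.ndarray] = {NM: np.zeros(N_CHANNELS)}
    for i, cls in enumerate(ACTIVE_CLASSES):
        g = np.zeros(N_CHANNELS)
        g[i] = 1.0
        gains[cls] = g
    return GeneratorParams(
        channel_gain=gains,
        baseline_sd=0.02,
        amplitude_jitter_sd=0.0,
        force_mod_depth=0.0,
        seed=seed,
    )


def _smoothed_activation(
    levels: np.ndarray, seg_bounds: list[tuple[int, int]], fs: float,
    rise_ms: float, fall_ms: float,
) -> np.ndarray:
    """First-order response of one channel's gain profile.

    ``levels[i]`` is the target level of segment ``i``; within each segment
    the response relaxes exponentially from its entry value toward the
    target, with the rise constant when increasing and the fall constant
    when decreasing. Exact, segment-by-segment solution.
    """
    n = seg_bounds[-1][1]
    out = np.empty(n)
    value = levels[0]  # start settled at the first segment's level
    for (a, b), target in zip(seg_bounds, levels):
        tau_ms = rise_ms if target > value else fall_ms
        tau = max(tau_ms, 1e-9) * fs / 1000.0
        t = np.arange(b - a)
        out[a:b] = target + (value - target) * np.exp(-t / tau)
        value = out[b - 1]
    return out


def generate_session(
    protocol: SessionProtocol,
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
) -> SignalRecording:
    """Generate one synthetic EMG + MMG session following ``protocol``.

    The pseudo-random stream is consumed in a fixed order: (1) one
    amplitude-jitter and one force-modulation-phase draw per active
    segment, in protocol order; (2) the EMG activation-noise matrix;
    (3) the EMG baseline-noise matrix; (4) the MMG noise vector.
    """
    params = params or GeneratorParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = protocol.sampling_rate
    seg = protocol.segment_samples()
    bounds: list[tuple[int, int]] = []
    pos = 0
    for _, ns in seg:
        bounds.append((pos, pos + ns))
        pos += ns
    n = pos
    labels = protocol.labels()

    # (1) per-segment draws, protocol order
    jitter: list[float] = []
    phase: list[float] = []
    for cls, _ in seg:
        if cls != NM:
            jitter.append(float(np.exp(rng.normal(0.0, params.amplitude_jitter_sd))))
            phase.append(float(rng.uniform(0.0, 2.0 * np.pi)))
        else:
            jitter.append(1.0)
            phase.append(0.0)

    # slowly-varying drive (force variability) per sample
    drive = np.ones(n)
    for (a, b), (cls, _), jit, ph in zip(bounds, seg, jitter, phase):
        if cls == NM:
            continue
        t = np.arange(b - a) / fs
        mod = 1.0 + params.force_mod_depth * np.sin(
            2.0 * np.pi * params.force_mod_freq_hz * t + ph
        )
        drift = 1.0 + params.fatigue_drift * t
        drive[a:b] = np.clip(jit * mod * drift, 0.0, None)

    # per-channel smoothed activation envelope of the gain square wave
    envelope = np.empty((N_CHANNELS, n))
    for ch in range(N_CHANNELS):
        levels = np.array([params.channel_gain[cls][ch] for cls, _ in seg])
        envelope[ch] = _smoothed_activation(
            levels, bounds, fs, params.envelope_rise_ms, params.envelope_fall_ms
        )

    # (2) activation noise, (3) baseline noise
    act_noise = rng.standard_normal((N_CHANNELS, n))
    base_noise = rng.standard_normal((N_CHANNELS, n))
    emg = envelope * drive[None, :] * act_noise + params.baseline_sd * base_noise

    # MMG: lagged trapezoid with an onset overshoot pulse, per contraction
    mmg_env = np.zeros(n)
    lag = int(round(params.mmg_lag_ms * fs / 1000.0))
    rise = max(1, int(round(params.mmg_rise_ms * fs / 1000.0)))
    fall = max(1, int(round(params.mmg_fall_ms * fs / 1000.0)))
    decay = max(1.0, params.mmg_overshoot_decay_ms * fs / 1000.0)
    for (a, b), (cls, _), jit in zip(bounds, seg, jitter):
        if cls == NM:
            continue
        t_on, t_off = a + lag, b + lag
        stop = min(t_off + fall, n)
        if t_on >= n:
            continue
        k = np.arange(t_on, stop)
        trap = np.minimum(1.0, (k - t_on + 1) / rise)
        trap = np.minimum(trap, np.maximum(0.0, (t_off + fall - k) / fall))
        pulse = 1.0 + (params.mmg_overshoot - 1.0) * np.exp(-(k - t_on) / decay)
        level = params.mmg_plateau[cls] * jit ** 0.5
        mmg_env[t_on:stop] = np.maximum(mmg_env[t_on:stop], level * trap * pulse)

    # (4) MMG noise
    mmg = mmg_env + params.mmg_noise_sd * rng.standard_normal(n)

    return SignalRecording(emg=emg, mmg=mmg, labels=labels, sampling_rate=fs)


def generate_offline_dataset(
    params: GeneratorParams | None = None,
    protocol: SessionProtocol | None = None,
) -> tuple[SignalRecording, SignalRecording]:
    """Training and testing sessions under the offline protocol.

    Both sessions share the protocol and parameters but take independent
    noise draws from a single seeded stream (training first).
    """
    params = params or GeneratorParams()
    protocol = protocol or offline_protocol()
    rng = np.random.default_rng(params.seed)
    train = generate_session(protocol, params, rng)
    test = generate_session(protocol, params, rng)
    return train, test


def corrupt_outputs(
    oco,
    error_rate: float,
    burst_len: int,
    seed: int,
    transient_fraction: float = 2.0 / 3.0,
) -> np.ndarray:
    """Inject wrong active classes into a classifier output stream.

    Emulates the two error textures of real online myoelectric tests:
    *sustained* misclassification episodes during constant contraction
    (typically late in the contraction, e.g. under muscle fatigue), and
    isolated single-window *transients*. Each error episode is, with
    probability ``transient_fraction``, a single corrupted window placed
    uniformly within the active (non-NM) runs; otherwise it is a burst of
    ``burst_len`` consecutive active windows carrying one wrong class,
    placed with a quadratic late-in-contraction bias and truncated at run
    boundaries. The default transient fraction (2/3 of episodes, i.e.
    ~40% of the corrupted window mass) reflects the share of motion-phase
    errors that a 3-point majority vote is able to remove in published
    online tests. Placement stops once ``round(error_rate * n_active)``
    windows are corrupted, so the corrupted fraction of active windows
    matches ``error_rate``.

    Parameters
    ----------
    oco : sequence of motion-class labels (the original classification output)
    error_rate : fraction of active windows to corrupt, in [0, 1]
    burst_len : length of sustained bursts in windows, >= 1
    seed : seed for the placement stream
    transient_fraction : probability that an episode is a single-window
        transient rather than a sustained burst
    """
    if not 0.0 <= error_rate <= 1.0:
        raise InvalidParameterError("error_rate must be within [0, 1]")
    if burst_len < 1:
        raise InvalidParameterError("burst_len must be >= 1")
    if not 0.0 <= transient_fraction <= 1.0:
        raise InvalidParameterError("transient_fraction must be within [0, 1]")
    seq = np.array([as_label(c) for c in oco], dtype="<U2")
    out = seq.copy()
    active = np.flatnonzero(seq != NM)
    n_active = active.size
    target = int(round(error_rate * n_active))
    if target == 0:
        return out

    # maximal runs of consecutive active window indices
    runs: list[np.ndarray] = []
    if n_active:
        cut = np.flatnonzero(np.diff(active) > 1) + 1
        runs = np.split(active, cut)
    # late-in-contraction placement weight for every active window
    weight = np.concatenate(
        [np.arange(1, r.size + 1, dtype=float) ** 2 for r in runs]
    )
    run_of = np.concatenate([np.full(r.size, i) for i, r in enumerate(runs)])
    pos_in_run = np.concatenate([np.arange(r.size) for r in runs])

    rng = np.random.default_rng(seed)
    idx_of = {int(wdx): i for i, wdx in enumerate(active)}
    corrupted = np.zeros(n_active, dtype=bool)
    count = 0
    actives = list(ACTIVE_CLASSES)
    while count < target:
        transient = rng.random() < transient_fraction
        length = 1 if transient else burst_len
        w = np.where(corrupted, 0.0, np.ones(n_active) if transient else weight)
        total = w.sum()
        if total <= 0:
            break
        s = int(rng.choice(n_active, p=w / total))
        run = runs[run_of[s]]
        burst = np.arange(pos_in_run[s], min(pos_in_run[s] + length, run.size))
        wrong = str(rng.choice([c for c in actives if c != seq[run[burst[0]]]]))
        for p in burst:
            if count >= target:
                break
            gi = idx_of[int(run[p])]
            if corrupted[gi]:
                continue
            cls = wrong
            if cls == seq[run[p]]:
                cls = str(rng.choice([c for c in actives if c != seq[run[p]]]))
            out[run[p]] = cls
            corrupted[gi] = True
            count += 1
    return out
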