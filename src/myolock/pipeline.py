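"""End-to-end orchestration: train, calibrate, run online, evaluate.

These helpers wire the modules together the way a control-session would:
an offline session trains the classifier and calibrates all three
detectors' thresholds; an online session is then classified per window and
each processing scenario (raw output, 3-point majority vote, or the
locking strategy under MAV/TKE/MMG) is evaluated against the designated
prompt sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectors import (
    ThresholdSet,
    baseline_window_mask,
    calibrate_emg_threshold,
    calibrate_mmg_thresholds,
    check_emg_calibration,
    ext_mav,
    ext_mmg,
    ext_tke,
)
from .features import WindowSpec, build_feature_matrix, per_class_feature_matrix, segment
from .lda import ConfusionMatrix, LDAModel, crossval, fit_lda
from .metrics import MetricReport, designated_from_recording, evaluate
from .motions import NM
from .postprocess import SCENARIOS, PostprocConfig, StateTrace, run_scenario
from .signals import SignalRecording
from .synth import (
    GeneratorParams,
    corrupt_outputs,
    generate_session,
    offline_protocol,
    online_protocol,
)


def calibrate_thresholds(
    recording: SignalRecording,
    window_spec: WindowSpec | None = None,
    deadband: float = 0.0,
    guard_ms: float = 300.0,
    ipv_span_ms: float = 500.0,
    ddof: int = 0,
) -> dict[str, ThresholdSet]:
    """Calibrate MAV, TKE and MMG thresholds from a training recording.

    The EMG-derived detectors use rest-window baselines (with a post-offset
    guard) and the mean + 3 SD rule; MMG uses the IPV / plateau rules. A
    usability check warns when an EMG threshold reaches into the active
    range, mirroring subjects for whom those thresholds are undeterminable.
    """
    window_spec = window_spec or WindowSpec()
    windows = segment(recording, window_spec)
    fm = build_feature_matrix(recording, window_spec, deadband)
    mav = ext_mav(fm)
    tke = ext_tke(recording, windows)
    rest = baseline_window_mask(recording, windows, guard_ms)
    active = windows.labels != NM
    out: dict[str, ThresholdSet] = {}
    for series in (mav, tke):
        th = calibrate_emg_threshold(series.values[rest], kind=series.kind, ddof=ddof)
        check_emg_calibration(th, series.values[active])
        out[series.kind] = th
    out["MMG"] = calibrate_mmg_thresholds(recording, ipv_span_ms)
    return out


@dataclass
class TrainedSystem:
    """A fitted classifier plus calibrated thresholds and run settings."""

    model: LDAModel
    thresholds: dict[str, ThresholdSet]
    window_spec: WindowSpec
    deadband: float
    config: PostprocConfig
    cv_error: float
    confusion: ConfusionMatrix
    params: GeneratorParams | None = None


def train_system(
    params: GeneratorParams | None = None,
    window_spec: WindowSpec | None = None,
    deadband: float = 0.0,
    folds: int = 5,
    cv_seed: int = 0,
    config: PostprocConfig | None = None,
    train_recording: SignalRecording | None = None,
) -> TrainedSystem:
    """Train and calibrate from an offline session.

    With no explicit recording, a synthetic offline session is generated
    from ``params`` (protocol: each motion 4 s, rest 3 s, four
    repetitions). Cross-validation runs on the per-class feature matrix;
    the final model is fit on all of it.
    """
    params = params or GeneratorParams()
    window_spec = window_spec or WindowSpec()
    if train_recording is None:
        train_recording = generate_session(offline_protocol(), params)
    fm = per_class_feature_matrix(train_recording, window_spec, deadband)
    cv_error, confusion = crossval(fm, folds=folds, seed=cv_seed)
    model = fit_lda(fm)
    thresholds = calibrate_thresholds(train_recording, window_spec, deadband)
    return TrainedSystem(
        model=model,
        thresholds=thresholds,
        window_spec=window_spec,
        deadband=deadband,
        config=config or PostprocConfig(),
        cv_error=cv_error,
        confusion=confusion,
        params=params,
    )


@dataclass
class OnlineResult:
    """Everything one online session produced, per scenario."""

    designated: np.ndarray
    oco: np.ndarray  # the (possibly corrupted) classifier stream
    outputs: dict[str, np.ndarray]
    traces: dict[str, StateTrace | None]
    detector_values: dict[str, np.ndarray]
    reports: dict[str, MetricReport] = field(default_factory=dict)

    def evaluate_all(self) -> dict[str, MetricReport]:
        self.reports = {
            name: evaluate(self.designated, out) for name, out in self.outputs.items()
        }
        return self.reports


def run_online_session(
    system: TrainedSystem,
    recording: SignalRecording | None = None,
    session_seed: int | None = None,
    scenarios: tuple[str, ...] = SCENARIOS,
    corrupt: tuple[float, int, int] | None = None,
) -> OnlineResult:
    """Run the online task under every requested scenario.

    With no explicit recording, a synthetic online session (the designated
    WP-WE-HO-WS-HC-WF task) is generated from the system's generator
    parameters reseeded with ``session_seed``. ``corrupt`` injects
    misclassification bursts into the classifier stream as
    ``(error_rate, burst_len, seed)`` before postprocessing. Detector
    values of every window are kept for threshold-sensitivity replays.
    """
    if recording is None:
        params = (system.params or GeneratorParams()).replace(
            seed=session_seed if session_seed is not None else 0
        )
        recording = generate_session(online_protocol(), params)
    designated = designated_from_recording(recording, system.window_spec)
    fm = build_feature_matrix(recording, system.window_spec, system.deadband)
    from .lda import predict_lda

    oco = predict_lda(system.model, fm)
    if corrupt is not None:
        rate, burst, seed = corrupt
        oco = corrupt_outputs(oco, rate, burst, seed)
    outputs: dict[str, np.ndarray] = {}
    traces: dict[str, StateTrace | None] = {}
    det_values: dict[str, np.ndarray] = {}
    for name in scenarios:
        thresholds = system.thresholds.get(name)
        output, _, trace, det = run_scenario(
            recording,
            system.model,
            thresholds,
            name,
            system.window_spec,
            system.deadband,
            system.config,
            oco=oco,
        )
        outputs[name] = output
        traces[name] = trace
        det_values[name] = det
    result = OnlineResult(
        designated=designated,
        oco=oco,
        outputs=outputs,
        traces=traces,
        detector_values=det_values,
    )
    result.evaluate_all()
    return result
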