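"""The six-state locking postprocessor and the 3-point majority vote."""

import numpy as np
import pytest

import myolock as ml
from _oracle import reference_postprocess
from conftest import random_stream
from myolock.errors import (
    IncompleteCalibrationError,
    InvalidConfigurationError,
    InvalidInputError,
)


def run(detector, oco, onset=1.0, offset=None, offset_map=None, **cfg):
    kind = "MMG" if offset_map is not None else "MAV"
    if offset is None and offset_map is None:
        offset = onset
    thresholds = ml.ThresholdSet(
        kind=kind, onset=onset, offset=offset, offset_map=offset_map
    )
    series = ml.DetectorSeries(kind=kind, values=np.asarray(detector, float))
    config = ml.PostprocConfig(**cfg) if cfg else None
    return ml.run_locking_postprocessor(series, oco, thresholds, config)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "oco,expected",
        [
            (list("AABAA"), list("AAAAA")),
            (list("ABBA"), list("ABBB")),
            (list("AAAA"), list("AAAA")),
        ],
    )
    def test_three_point_vote(self, oco, expected):
        trans = {"A": "HC", "B": "HO", "C": "WE"}
        out = ml.majority_vote_3([trans[c] for c in oco])
        assert list(out) == [trans[c] for c in expected]

    def test_three_distinct_candidates_retain_previous_output(self):
        out = ml.majority_vote_3(["HC", "HC", "HC", "HO", "WE", "WE"])
        # window 4 sees {HC, HO, WE}: retains the previously emitted HC
        assert list(out) == ["HC", "HC", "HC", "HC", "HC", "WE"]

    def test_two_consecutive_errors_survive_the_vote(self):
        out = ml.majority_vote_3(["HC", "HC", "HO", "HO", "HC", "HC"])
        assert "HO" in out  # the documented weakness of 3MV


class TestStateMachine:
    def test_detector_below_onset_forces_nm_everywhere(self):
        oco = ["HC", "HO", "WS", "HC", "HC", "HC", "WE", "WF"]
        out, trace = run(np.full(8, 0.5), oco)
        assert (out == "NM").all()
        assert set(trace.states) == {1}

    def test_decision_is_majority_of_first_six_active_and_locks(self):
        oco = ["HC", "HC", "HO", "HC", "HC", "HC"] + ["HO"] * 6
        out, trace = run(np.full(12, 2.0), oco)
        # decision stage passes OCO through; lock then emits HC regardless
        assert list(out[:6]) == oco[:6]
        assert (out[6:] == "HC").all()
        assert (trace.states[:6] == 2).all()
        assert (trace.states[6:] == 4).all()

    def test_nm_windows_in_decision_stage_do_not_count_as_active(self):
        oco = ["HC", "NM", "HC", "HC", "NM", "HC", "HC", "HC", "HO"]
        out, trace = run(np.full(9, 2.0), oco)
        # six active windows accrue only at window 7; window 8 is locked
        assert (trace.states[:8] == 2).all()
        assert trace.states[8] == 4
        assert out[8] == "HC"
        assert out[1] == "NM"  # state 2 passes OCO through verbatim

    def test_aborted_onset_emits_oco_then_returns_to_rest(self):
        detector = [0.2, 2.0, 2.0, 2.0, 0.2, 0.2]
        oco = ["NM", "HC", "HC", "HO", "HC", "HC"]
        out, trace = run(detector, oco)
        assert list(out) == ["NM", "HC", "HC", "HO", "NM", "NM"]
        assert list(trace.states) == [1, 2, 2, 2, 3, 1]

    def test_mmg_dip_unlocks_and_relocks_without_new_decision(self):
        # lock on HC, detector dips between onset and offset for 2 windows
        detector = [3.0] * 7 + [1.2, 1.2] + [3.0] * 3
        oco = ["HC"] * 6 + ["HO"] * 6
        out, trace = run(
            detector, oco, onset=1.0, offset_map={"HC": 2.0, "HO": 2.0}
        )
        assert (trace.states[6:7] == 4).all()
        assert list(trace.states[7:9]) == [5, 5]
        assert list(out[7:9]) == ["NM", "NM"]
        # resumes the same decision with no second decision stage
        assert list(trace.states[9:]) == [4, 4, 4]
        assert (out[9:] == "HC").all()

    def test_mmg_long_dip_forces_a_new_decision(self):
        detector = [3.0] * 7 + [1.2] * 4 + [3.0] * 7
        oco = ["HC"] * 6 + ["HO"] * 12
        out, trace = run(
            detector, oco, onset=1.0, offset_map={"HC": 2.0, "HO": 2.0}
        )
        assert list(trace.states[7:11]) == [5, 5, 5, 2]
        # the re-made decision follows the new OCO majority
        assert trace.states[-1] == 4
        assert out[-1] == "HO"

    def test_release_requires_minimum_rest_before_next_decision(self):
        detector = [2.0] * 7 + [0.1, 2.0, 0.1, 0.1, 0.1, 2.0, 2.0]
        oco = ["HC"] * 14
        out, trace = run(detector, oco, min_rest_windows=3)
        assert trace.states[7] == 6  # release window
        # detector pops above onset before 3 rest windows: still state 6
        assert trace.states[8] == 6
        assert out[8] == "NM"
        assert list(trace.states[9:12]) == [6, 6, 6]
        # rest satisfied; next onset re-enters the decision stage
        assert list(trace.states[12:]) == [2, 2]

    def test_equal_thresholds_never_reach_state_5(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            detector, oco, thresholds = random_stream(rng, 80, hysteresis=False)
            series = ml.DetectorSeries(kind="MAV", values=detector)
            _, trace = ml.run_locking_postprocessor(series, oco, thresholds)
            assert 5 not in trace.states

    def test_locked_output_constant_within_every_state4_run(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            detector, oco, thresholds = random_stream(rng, 120, hysteresis=True)
            series = ml.DetectorSeries(kind="MMG", values=detector)
            out, trace = ml.run_locking_postprocessor(series, oco, thresholds)
            for a, b, cls in trace.locked_runs():
                assert (out[a:b] == cls).all()
                assert cls != "NM"

    def test_nm_emitted_whenever_detector_below_onset(self):
        rng = np.random.default_rng(2)
        for hysteresis in (False, True):
            for trial in range(25):
                detector, oco, thresholds = random_stream(rng, 100, hysteresis)
                series = ml.DetectorSeries(kind=thresholds.kind, values=detector)
                out, _ = ml.run_locking_postprocessor(series, oco, thresholds)
                assert (out[detector < thresholds.onset] == "NM").all()

    @pytest.mark.parametrize("hysteresis", [False, True])
    def test_matches_reference_interpreter_on_random_streams(self, hysteresis):
        rng = np.random.default_rng(3 + hysteresis)
        for trial in range(200):
            n = int(rng.integers(5, 120))
            detector, oco, thresholds = random_stream(rng, n, hysteresis)
            series = ml.DetectorSeries(kind=thresholds.kind, values=detector)
            out, trace = ml.run_locking_postprocessor(series, oco, thresholds)
            ref_out, ref_states = reference_postprocess(
                detector, list(oco), thresholds.onset, thresholds.offset_for
            )
            assert list(out) == ref_out
            assert list(trace.states) == ref_states

    def test_emitted_matches_state_semantics(self):
        rng = np.random.default_rng(5)
        detector, oco, thresholds = random_stream(rng, 300, hysteresis=True)
        series = ml.DetectorSeries(kind="MMG", values=detector)
        out, trace = ml.run_locking_postprocessor(series, oco, thresholds)
        rest_states = np.isin(trace.states, (1, 3, 5, 6))
        assert (out[rest_states] == "NM").all()
        assert (out[trace.states == 4] == trace.decision[trace.states == 4]).all()

    def test_length_and_kind_mismatches_rejected(self):
        series = ml.DetectorSeries(kind="MAV", values=np.ones(5))
        thresholds = ml.ThresholdSet(kind="MAV", onset=1.0, offset=1.0)
        with pytest.raises(InvalidInputError):
            ml.run_locking_postprocessor(series, ["HC"] * 4, thresholds)
        tke_th = ml.ThresholdSet(kind="TKE", onset=1.0, offset=1.0)
        with pytest.raises(InvalidInputError):
            ml.run_locking_postprocessor(series, ["HC"] * 5, tke_th)

    def test_unknown_decision_class_in_offset_map_rejected(self):
        with pytest.raises(IncompleteCalibrationError):
            run(np.full(8, 3.0), ["WS"] * 8, onset=1.0, offset_map={"HC": 2.0})


class TestRunScenario:
    def test_oco_scenario_is_a_passthrough(self, default_system):
        rec = ml.generate_session(
            ml.online_protocol(trials=1), ml.GeneratorParams(seed=9)
        )
        out, oco, trace, det = ml.run_scenario(
            rec, default_system.model, None, "OCO", default_system.window_spec
        )
        assert (out == oco).all()
        assert trace is None

    def test_3mv_scenario_equals_majority_vote_of_oco(self, default_system):
        rec = ml.generate_session(
            ml.online_protocol(trials=1), ml.GeneratorParams(seed=9)
        )
        out, oco, _, _ = ml.run_scenario(
            rec, default_system.model, None, "3MV", default_system.window_spec
        )
        assert (out == ml.majority_vote_3(oco)).all()

    def test_locking_scenarios_require_thresholds(self, default_system):
        rec = ml.generate_session(
            ml.online_protocol(trials=1), ml.GeneratorParams(seed=9)
        )
        with pytest.raises(InvalidConfigurationError):
            ml.run_scenario(rec, default_system.model, None, "MMG")
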