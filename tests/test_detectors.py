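"""Onset detectors (extMAV / extTKE / extMMG) and threshold calibration."""

import numpy as np
import pytest

import myolock as ml
from myolock.detectors import baseline_window_mask, check_emg_calibration
from myolock.errors import (
    CalibrationWarning,
    IncompleteCalibrationError,
    InsufficientBaselineError,
    InvalidInputError,
)
from myolock.features import default_columns


def recording_from_emg(emg, mmg=None, labels=None, fs=1000.0):
    emg = np.asarray(emg, dtype=float)
    n = emg.shape[1]
    return ml.SignalRecording(
        emg=emg,
        mmg=np.zeros(n) if mmg is None else np.asarray(mmg, dtype=float),
        labels=np.full(n, "NM", dtype="<U2") if labels is None else labels,
        sampling_rate=fs,
    )


class TestTKE:
    def test_constant_signal_has_zero_energy(self):
        assert np.allclose(ml.tke_pointwise(np.full(100, 3.7)), 0.0)

    def test_linear_ramp_has_unit_energy(self):
        assert np.allclose(ml.tke_pointwise(np.arange(50.0)), 1.0)

    @pytest.mark.parametrize("amplitude", [1.0, 2.0, 10.0])
    @pytest.mark.parametrize("omega", [0.1, 0.5, 1.0])
    @pytest.mark.parametrize("phi", [0.0, 1.2])
    def test_sinusoid_closed_form(self, amplitude, omega, phi):
        k = np.arange(500)
        x = amplitude * np.cos(omega * k + phi)
        expected = amplitude**2 * np.sin(omega) ** 2
        values = ml.tke_pointwise(x)
        assert np.max(np.abs(values - expected)) <= 1e-9 * expected

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidInputError):
            ml.tke_pointwise([1.0, 2.0])


class TestExtraction:
    def test_ext_mav_sums_channel_mavs(self):
        values = np.zeros((2, 24))
        cols = default_columns()
        mav_idx = [i for i, c in enumerate(cols) if c.endswith("_mav")]
        values[0, mav_idx] = 1.0
        values[1, mav_idx[2]] = 2.0
        fm = ml.FeatureMatrix(
            values=values, labels=np.array(["HC", "HC"]), columns=cols
        )
        series = ml.ext_mav(fm)
        assert series.values == pytest.approx([6.0, 2.0])

    def test_ext_mav_scales_linearly_with_the_signal(self):
        rng = np.random.default_rng(0)
        rec = recording_from_emg(rng.standard_normal((6, 1000)))
        scaled = recording_from_emg(3.0 * rec.emg)
        a = ml.ext_mav(ml.build_feature_matrix(rec))
        b = ml.ext_mav(ml.build_feature_matrix(scaled))
        np.testing.assert_allclose(b.values, 3.0 * a.values)

    def test_ext_tke_of_zero_signal_is_zero(self):
        rec = recording_from_emg(np.zeros((6, 600)))
        series = ml.ext_tke(rec, ml.segment(rec))
        assert not series.values.any()

    def test_ext_tke_single_ramp_channel_gives_ones(self):
        emg = np.zeros((6, 600))
        emg[2] = np.arange(600.0)
        rec = recording_from_emg(emg)
        series = ml.ext_tke(rec, ml.segment(rec))
        assert np.allclose(series.values, 1.0)

    def test_ext_tke_matches_brute_force_window_loop(self):
        rng = np.random.default_rng(1)
        rec = recording_from_emg(rng.standard_normal((6, 1000)))
        windows = ml.segment(rec)
        series = ml.ext_tke(rec, windows)
        for w, (a, b) in enumerate(windows.bounds()):
            best = -np.inf
            for k in range(a + 1, b - 1):
                total = 0.0
                for ch in range(6):
                    x = rec.emg[ch]
                    total += x[k] ** 2 - x[k - 1] * x[k + 1]
                best = max(best, total)
            assert series.values[w] == pytest.approx(best)

    def test_ext_mmg_matches_brute_force_window_max(self):
        rng = np.random.default_rng(2)
        rec = recording_from_emg(
            np.zeros((6, 1000)), mmg=rng.standard_normal(1000)
        )
        windows = ml.segment(rec)
        series = ml.ext_mmg(rec, windows)
        for w, (a, b) in enumerate(windows.bounds()):
            assert series.values[w] == pytest.approx(max(rec.mmg[a:b]))

    def test_ext_mmg_simple_values(self):
        rec = recording_from_emg(np.zeros((6, 300)), mmg=np.zeros(300))
        rec.mmg[:150] = [0.0, 2.0, 1.0] * 50
        windows = ml.segment(rec)
        series = ml.ext_mmg(rec, windows)
        assert series.values[0] == 2.0


class TestEMGThresholds:
    def test_constant_baseline_gives_threshold_at_the_constant(self):
        th = ml.calibrate_emg_threshold(np.full(10, 2.5), kind="MAV")
        assert th.onset == pytest.approx(2.5)
        assert th.offset == th.onset

    def test_population_sd_convention(self):
        # mean 1, population SD 1 -> threshold 1 + 3*1 = 4
        th = ml.calibrate_emg_threshold(np.array([0.0, 2.0, 0.0, 2.0]), kind="TKE")
        assert th.onset == pytest.approx(4.0)
        th1 = ml.calibrate_emg_threshold(
            np.array([0.0, 2.0, 0.0, 2.0]), kind="TKE", ddof=1
        )
        assert th1.onset > th.onset  # sample SD is larger

    def test_insufficient_baseline_rejected(self):
        with pytest.raises(InsufficientBaselineError):
            ml.calibrate_emg_threshold(np.array([1.0]), kind="MAV")

    def test_unusable_threshold_triggers_warning(self):
        th = ml.ThresholdSet(kind="MAV", onset=10.0, offset=10.0)
        with pytest.warns(CalibrationWarning):
            ok = check_emg_calibration(th, np.linspace(1.0, 5.0, 50))
        assert not ok
        assert check_emg_calibration(th, np.linspace(100.0, 200.0, 50))

    def test_baseline_mask_applies_post_offset_guard(self):
        labels = np.full(2000, "NM", dtype="<U2")
        labels[500:1000] = "HC"
        rec = recording_from_emg(np.zeros((6, 2000)), labels=labels)
        windows = ml.segment(rec)
        mask = baseline_window_mask(rec, windows, guard_ms=300)
        starts = windows.starts[mask]
        # no baseline window may start within 300 ms after the offset at 1000
        assert not any(1000 <= s < 1300 for s in starts)
        # and none may overlap the contraction itself
        for a, b in ml.segment(rec).bounds():
            if a in starts:
                assert not (labels[a:b] != "NM").any()
        assert any(s >= 1300 for s in starts)
        assert any(s < 350 for s in starts)


class TestMMGThresholds:
    def test_ipv_of_overshoot_trapezoid(self):
        trace = np.concatenate([np.zeros(100), np.full(400, 2.0), np.zeros(100)])
        trace[100:150] = 3.0  # initial peak
        assert ml.estimate_ipv(trace, 100, 1000.0) == pytest.approx(3.0)

    def test_ipv_without_overshoot_equals_plateau(self):
        trace = np.concatenate([np.zeros(100), np.full(600, 2.0)])
        assert ml.estimate_ipv(trace, 100, 1000.0) == pytest.approx(2.0)

    def test_ipv_of_silent_trace_warns(self):
        with pytest.warns(CalibrationWarning):
            assert ml.estimate_ipv(np.zeros(500), 0, 1000.0) == 0.0

    def test_plateau_of_ideal_trapezoid(self):
        trace = np.concatenate([np.zeros(50), np.full(400, 2.0), np.zeros(50)])
        assert ml.estimate_plateau(trace, (50, 450)) == pytest.approx(2.0)

    def test_plateau_excludes_ramps_and_overshoot(self):
        trace = np.concatenate([np.linspace(0, 4, 100), np.full(300, 2.0)])
        assert ml.estimate_plateau(trace, (0, 400)) == pytest.approx(2.0)

    def test_plateau_under_noise_is_unbiased(self):
        rng = np.random.default_rng(3)
        estimates = [
            ml.estimate_plateau(2.0 + 0.1 * rng.standard_normal(2000), (0, 2000))
            for _ in range(50)
        ]
        assert abs(np.mean(estimates) - 2.0) < 0.05

    def test_constant_trace_plateau_is_the_constant(self):
        assert ml.estimate_plateau(np.full(100, 1.3), (0, 100)) == pytest.approx(1.3)

    def test_short_span_rejected(self):
        with pytest.raises(InvalidInputError):
            ml.estimate_plateau(np.zeros(100), (10, 12))

    def test_onset_is_one_third_of_global_ipv_minimum(self):
        # three single-trial classes with IPVs 3, 6, 9 and plateaus 2.4/3.0
        pieces, labels = [], []

        def block(cls, ipv, plateau, n=1000):
            x = np.full(n, plateau)
            x[:100] = ipv
            pieces.extend([np.zeros(500), x])
            labels.extend(["NM"] * 500 + [cls] * n)

        block("HC", 3.0, 2.4)
        block("HO", 6.0, 3.0)
        block("WE", 9.0, 2.4)
        block("HC", 5.0, 3.0)  # second HC trial
        pieces.append(np.zeros(500))
        labels.extend(["NM"] * 500)
        mmg = np.concatenate(pieces)
        rec = recording_from_emg(
            np.zeros((6, mmg.size)), mmg=mmg,
            labels=np.array(labels, dtype="<U2"),
        )
        th = ml.calibrate_mmg_thresholds(rec, required_classes=("HC", "HO", "WE"))
        assert th.onset == pytest.approx(1.0)  # (1/3) * min{3, 6, 9, 5}
        assert th.offset_for("HC") == pytest.approx(2.0 / 3.0 * 2.4)
        assert th.offset_for("HO") == pytest.approx(2.0)
        # provenance reproduces the raw calibration inputs
        assert th.provenance["ipv"]["HC"] == pytest.approx([3.0, 5.0])
        assert th.provenance["plateau"]["HO"] == pytest.approx([3.0])

    def test_missing_class_rejected(self):
        labels = np.array(["NM"] * 200 + ["HC"] * 500 + ["NM"] * 200, dtype="<U2")
        rec = recording_from_emg(
            np.zeros((6, 900)), mmg=np.ones(900), labels=labels
        )
        with pytest.raises(IncompleteCalibrationError):
            ml.calibrate_mmg_thresholds(rec)

    def test_offset_lookup_for_uncalibrated_class_rejected(self):
        th = ml.ThresholdSet(kind="MMG", onset=1.0, offset_map={"HC": 2.0})
        with pytest.raises(IncompleteCalibrationError):
            th.offset_for("WS")
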