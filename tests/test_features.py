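"""Feature-extraction oracles: conditioning, fiducials, pressures,
respiration, the 13 formulas, baseline normalization, derived indices."""

import numpy as np
import pytest

from cardioloop import synth, features
from cardioloop.features import (
    FeatureConfig, condition_epoch, detect_r_peaks, detect_fiducials,
    detect_bp_extrema, breath_rate, compute_features, window_average,
    baseline_normalize, derived_indices, step_grid,
)
from conftest import short_protocol


class TestConditioning:
    def test_constant_signal_preserved(self):
        x = np.full(20_000, 3.7)
        ecg, abp = condition_epoch(x, x)
        assert ecg.size == 1000
        # ignore the FIR transient at the edges
        assert np.allclose(ecg[30:-30], 3.7, rtol=0.005)

    def test_sine_amplitude_preserved(self):
        """A 10 Hz sinusoid survives decimation within 1 %."""
        t = np.arange(100_000) / 10_000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        ecg, _ = condition_epoch(x, x)
        assert ecg.size == 5000
        interior = ecg[500:-500]
        assert np.max(np.abs(interior)) == pytest.approx(1.0, rel=0.01)

    def test_one_second_gives_500_samples(self):
        x = np.zeros(10_000)
        ecg, _ = condition_epoch(x, x)
        assert ecg.size == 500

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            condition_epoch(np.array([]), np.array([]))


class TestRPeaks:
    def test_fixed_rate_rr_recovered(self):
        """Synthetic 400 bpm record: detected RR = 150 ms within a sample."""
        subject = synth.draw_subject(np.random.default_rng(2), seed=5).noiseless()
        subject = type(subject)(**{**subject.__dict__, "resting_hr": 400.0})
        rec = synth.generate_recording(short_protocol("rest"), subject)
        ecg, _ = condition_epoch(rec.ecg, rec.abp)
        times, levels, flagged = detect_r_peaks(ecg, 500.0)
        assert not flagged
        rr = np.diff(times)
        assert np.abs(rr - 0.150).max() < 0.002

    def test_flat_line_flagged(self):
        times, levels, flagged = detect_r_peaks(np.zeros(5000), 500.0)
        assert flagged and times.size == 0

    def test_injected_pvc_creates_short_rr(self, short_record):
        rec = synth.inject_arrhythmia(short_record, "PVC", rate=6.0, seed=1)
        ecg, _ = condition_epoch(rec.ecg, rec.abp)
        times, _, _ = detect_r_peaks(ecg, 500.0)
        rr = np.diff(times)
        # truth premature beats at 0.6 x RR appear in the detected series
        assert rr.min() < 0.72 * np.median(rr)


class TestFiducials:
    def test_noiseless_fiducials_match_truth(self, noiseless_record):
        """Every detected P/Ta/S/T point within 4 ms and 0.01 mV of truth."""
        rec = noiseless_record
        ecg, _ = condition_epoch(rec.ecg, rec.abp)
        r_times, r_levels, _ = detect_r_peaks(ecg, 500.0)
        beats = detect_fiducials(ecg, 500.0, r_times, r_levels)
        truth = rec.truth_beats
        # align each detected beat with the nearest truth beat
        idx = np.searchsorted(truth["t"], beats["r_time"])
        idx = np.clip(idx, 1, truth["t"].size - 1)
        left_closer = (np.abs(truth["t"][idx - 1] - beats["r_time"])
                       < np.abs(truth["t"][idx] - beats["r_time"]))
        idx = idx - left_closer
        near = np.abs(truth["t"][idx] - beats["r_time"]) < 0.02
        assert near.mean() > 0.98
        for name in ("p", "ta", "s", "t"):
            dt = beats[f"{name}_time"][near] - truth[f"{name}_time"][idx][near]
            dv = beats[f"{name}_level"][near] - truth[f"{name}_level"][idx][near]
            assert np.abs(dt).max() < 0.004, name
            assert np.abs(dv).max() < 0.01, name

    def test_zero_amplitude_p_reads_tp_reference(self):
        subject = synth.draw_subject(np.random.default_rng(3), seed=6).noiseless()
        subject = type(subject)(**{**subject.__dict__, "amp_p": 0.0})
        rec = synth.generate_recording(short_protocol("rest"), subject)
        ecg, _ = condition_epoch(rec.ecg, rec.abp)
        r_times, r_levels, _ = detect_r_peaks(ecg, 500.0)
        beats = detect_fiducials(ecg, 500.0, r_times, r_levels)
        assert np.abs(beats["p_level"] - beats["tp_level"]).max() < 0.005

    def test_fewer_than_two_r_peaks_empty(self):
        beats = detect_fiducials(np.zeros(1000), 500.0, np.array([0.5]), np.array([1.0]))
        assert beats["r_time"].size == 0
        assert beats["n_dropped"] == 0


class TestBloodPressure:
    def test_120_over_80(self):
        subject = synth.draw_subject(np.random.default_rng(4), seed=7).noiseless()
        subject = type(subject)(**{**subject.__dict__,
                                   "resting_sys": 120.0, "resting_dia": 80.0,
                                   "resp_mod": 0.0})
        rec = synth.generate_recording(short_protocol("rest"), subject)
        _, abp = condition_epoch(rec.ecg, rec.abp)
        pulses = detect_bp_extrema(abp, 500.0)
        assert not pulses["flagged"]
        assert np.mean(pulses["sys_p"]) == pytest.approx(120.0, abs=1.0)
        assert np.mean(pulses["dia_p"]) == pytest.approx(80.0, abs=1.0)
        # per-pulse pulse pressure matches the generator truth within 2 mmHg
        pp = pulses["sys_p"] - pulses["dia_p"]
        assert np.percentile(np.abs(pp - 40.0), 99) < 2.0

    def test_constant_pressure_flagged(self):
        pulses = detect_bp_extrema(np.full(5000, 90.0), 500.0)
        assert pulses["flagged"]


class TestBreathRate:
    def test_recovers_generator_rate(self):
        subject = synth.draw_subject(np.random.default_rng(5), seed=8).noiseless()
        subject = type(subject)(**{**subject.__dict__, "resting_breath": 60.0})
        rec = synth.generate_recording(short_protocol("rest"), subject)
        _, abp = condition_epoch(rec.ecg, rec.abp)
        assert breath_rate(abp, 500.0) == pytest.approx(60.0, abs=5.0)

    def test_doubling_rate_doubles_estimate(self):
        rng = np.random.default_rng(6)
        ests = []
        for brpm in (50.0, 100.0):
            subject = synth.draw_subject(rng, seed=9).noiseless()
            subject = type(subject)(**{**subject.__dict__, "resting_breath": brpm})
            rec = synth.generate_recording(short_protocol("rest"), subject)
            _, abp = condition_epoch(rec.ecg, rec.abp)
            ests.append(breath_rate(abp, 500.0))
        assert ests[1] / ests[0] == pytest.approx(2.0, rel=0.1)

    def test_no_modulation_flagged_zero(self):
        subject = synth.draw_subject(np.random.default_rng(7), seed=10).noiseless()
        subject = type(subject)(**{**subject.__dict__, "resp_mod": 0.0})
        rec = synth.generate_recording(short_protocol("rest"), subject)
        _, abp = condition_epoch(rec.ecg, rec.abp)
        assert breath_rate(abp, 500.0) == 0.0


class TestFormulas:
    """Hand-computed oracles for the printed formulas."""

    def _window(self, sys_p, dia_p, rr=0.15):
        beats = {k: np.array([]) for k in
                 ("r_time", "r_level", "rr", "p_time", "p_level", "ta_time",
                  "ta_level", "q_time", "q_level", "s_time", "s_level",
                  "t_time", "t_level", "tp_level")}
        pulses = {"sys_time": np.array([1.0]), "sys_p": np.array([sys_p]),
                  "dia_time": np.array([0.9]), "dia_p": np.array([dia_p])}
        return beats, pulses

    def test_map_and_pulse_pressure(self):
        beats, pulses = self._window(120.0, 80.0)
        v = compute_features(beats, pulses, 60.0)
        assert v[10] == pytest.approx(100.0)   # MAP = (120+80)/2
        assert v[11] == pytest.approx(40.0)    # PP = 120-80

    def test_heart_rate_from_rr(self):
        beats = {
            "r_time": np.array([0.0, 0.15]), "r_level": np.array([0.8, 0.8]),
            "rr": np.array([0.15, 0.15]),
            "p_time": np.array([-0.04, 0.11]), "p_level": np.array([0.1, 0.1]),
            "ta_time": np.array([-0.02, 0.13]), "ta_level": np.array([-0.05, -0.05]),
            "q_time": np.array([-0.008, 0.142]), "q_level": np.array([-0.1, -0.1]),
            "s_time": np.array([0.008, 0.158]), "s_level": np.array([-0.15, -0.15]),
            "t_time": np.array([0.045, 0.195]), "t_level": np.array([0.25, 0.25]),
            "tp_level": np.array([0.0, 0.0]),
        }
        pulses = {"sys_time": np.array([]), "sys_p": np.array([]),
                  "dia_time": np.array([]), "dia_p": np.array([])}
        v = compute_features(beats, pulses, 60.0)
        assert v[1] == pytest.approx(400.0)          # 60 / 0.15 s
        assert v[2] == pytest.approx(16.0)           # QRS ms
        assert v[3] == pytest.approx(45.0)           # RT ms
        assert v[4] == pytest.approx(37.0)           # ST ms
        assert v[7] == pytest.approx((0.25 + 0.15) / 0.037)   # ST slope

    def test_empty_window_is_nan_vector(self):
        beats, pulses = self._window(120.0, 80.0)
        pulses = {k: np.array([]) for k in pulses}
        v = compute_features(beats, pulses, 0.0)
        assert np.isnan(v[:12]).all()

    def test_rpp_qtc_qttq_oracles(self):
        """RPP = HR x SBP / 100; Bazett QTc; QT/TQ with TQ = RR - QT."""
        steps = step_grid(0.0, 1.0)
        X = np.full((steps.size, 13), np.nan)
        X[:, 1] = 400.0        # HR  -> RR = 150 ms
        X[:, 9] = 120.0        # SBP
        X[:, 2] = 16.0         # QRS -> QT approx = RT + QRS/2
        X[:, 3] = 52.0         # RT  -> QT = 60 ms
        X[:, 8] = 80.0
        X[:, 10] = 100.0; X[:, 11] = 40.0; X[:, 0] = 0; X[:, 4] = 0
        X[:, 5] = 0; X[:, 6] = 0; X[:, 7] = 0; X[:, 12] = 60
        frame = features.FeatureFrame(steps, X, np.full(steps.size, "rest", dtype=object),
                                      np.zeros(steps.size, dtype=bool))
        idx = derived_indices(frame)
        assert idx.rpp[0] == pytest.approx(480.0)            # (400 x 120)/100
        # QT = 60 ms, RR = 150 ms: QTc = 60/sqrt(150); QT/TQ = 60/90
        assert idx.qtc[0] == pytest.approx(60.0 / np.sqrt(150.0))
        assert idx.qt_tq[0] == pytest.approx(60.0 / 90.0)

    def test_qtc_printed_example(self):
        """QT 60 ms at RR 144 ms: QTc = 60/12 = 5.0."""
        steps = step_grid(0.0, 0.5)
        X = np.zeros((steps.size, 13))
        X[:, 1] = 60_000.0 / 144.0
        X[:, 9] = 120.0
        X[:, 2] = 16.0
        X[:, 3] = 52.0
        frame = features.FeatureFrame(steps, X, np.full(steps.size, "rest", dtype=object),
                                      np.zeros(steps.size, dtype=bool))
        idx = derived_indices(frame)
        assert idx.qtc[0] == pytest.approx(5.0)

    def test_qttq_undefined_when_tq_nonpositive(self):
        steps = step_grid(0.0, 0.5)
        X = np.zeros((steps.size, 13))
        X[:, 1] = 400.0          # RR 150 ms
        X[:, 2] = 20.0
        X[:, 3] = 145.0          # QT = 155 ms > RR
        frame = features.FeatureFrame(steps, X, np.full(steps.size, "rest", dtype=object),
                                      np.zeros(steps.size, dtype=bool))
        idx = derived_indices(frame)
        assert idx.flagged.all()
        assert np.isnan(idx.qt_tq).all()


class TestWindowing:
    def test_window_average_trailing_halfopen(self):
        times = np.array([0.5, 1.5, 2.5, 3.5])
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        steps = np.array([2.0, 4.0, 6.0, 10.0])
        out = window_average(times, vals, steps, width=4.0)
        assert out[0] == pytest.approx(1.5)    # events at 0.5 and 1.5
        assert out[1] == pytest.approx(2.5)    # all four events in [0, 4)
        assert out[2] == pytest.approx(3.5)    # events at 2.5 and 3.5
        assert np.isnan(out[3])                # no events in [6, 10)

    def test_step_grid_contract(self):
        """Output step count = floor((length - 4 s) / 0.1 s) + 1."""
        assert step_grid(4.0, 214.0).size == 2101
        assert step_grid(4.0, 64.0).size == 601

    def test_internal_consistency_and_grid(self, noiseless_frame):
        fr = noiseless_frame
        assert len(fr) == 2101
        ok = ~fr.missing
        assert np.allclose(fr.X[ok, 11], fr.X[ok, 9] - fr.X[ok, 8])
        assert np.allclose(fr.X[ok, 10], (fr.X[ok, 9] + fr.X[ok, 8]) / 2)
        assert (fr.X[ok, 9] > fr.X[ok, 8]).all()


class TestClosure:
    def test_all_13_features_match_truth(self, noiseless_record, noiseless_frame):
        """Master oracle: on a noiseless record every feature tracks the
        generator's ground truth within 2 % relative (or 1 unit) at every
        step after window fill."""
        truth = noiseless_record.truth_frame
        fr = noiseless_frame
        valid = ~(fr.missing | truth.missing)
        err = np.abs(fr.X[valid] - truth.X[valid])
        rel = err / np.maximum(np.abs(truth.X[valid]), 1e-9)
        ok = (rel <= 0.02) | (err <= 1.0)
        assert ok.all(), f"per-feature max rel err {rel.max(axis=0)}"

    def test_noise_robust_heart_rate(self):
        """ECG noise at 10 % of the R amplitude biases HR by < 2 bpm."""
        subject = synth.draw_subject(np.random.default_rng(8), seed=11).noiseless()
        subject = type(subject)(**{**subject.__dict__,
                                   "resting_hr": 400.0,
                                   "ecg_noise_mv": 0.08})
        rec = synth.generate_recording(short_protocol("rest"), subject)
        fr = features.extract_features(rec)
        ok = ~fr.missing
        assert abs(np.mean(fr.X[ok, 1]) - 400.0) < 2.0


class TestBaselineNormalize:
    def test_background_only_zero_mean_unit_sd(self, noiseless_frame):
        fr = noiseless_frame.copy()
        delta, z = baseline_normalize(fr)
        bg = (fr.step_times >= 4.0) & (fr.step_times < 34.0)
        assert np.abs(np.nanmean(z[bg], axis=0)).max() < 1e-6
        # noiseless features are nearly constant; SD floor keeps z finite
        assert np.isfinite(z[bg]).all()

    def test_offset_shifts_delta_exactly(self, noiseless_frame):
        fr = noiseless_frame.copy()
        fr2 = fr.copy()
        post = fr2.step_times >= 60.0
        fr2.X[post, 1] += 17.0
        d1, _ = baseline_normalize(fr)
        d2, _ = baseline_normalize(fr2)
        assert np.allclose(d2[post, 1] - d1[post, 1], 17.0)

    def test_dne_st_delta_negative(self, noiseless_frame):
        """Infusion-average Delta of ST epoch level is negative under D+NE."""
        fr = noiseless_frame.copy()
        delta, _ = baseline_normalize(fr)
        inf = fr.step_times >= 120.0
        assert np.nanmean(delta[inf, 0]) < -0.02

    def test_short_background_rejected(self, noiseless_frame):
        with pytest.raises(ValueError, match="background"):
            baseline_normalize(noiseless_frame.copy(), background=(4.0, 20.0))
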