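"""Simulator contracts: determinism, effect directions, dose monotonicity,
label balance, arrhythmia injection, plant behaviour, cohort structure."""

import numpy as np
import pytest

from cardioloop import synth, features
from conftest import short_protocol


def _subject(seed=1, noiseless=False):
    s = synth.draw_subject(np.random.default_rng(seed), seed=seed)
    return s.noiseless() if noiseless else s


class TestProtocol:
    def test_event_times_must_increase(self):
        with pytest.raises(ValueError):
            synth.InfusionProtocol(timeline={
                "stream_start": 0.0, "window_init": 4.0, "decode_start": 34.0,
                "infusion_start": 30.0, "end": 214.0})

    @pytest.mark.parametrize("kwargs", [
        {"agent": "caffeine"}, {"dose_scale": 0.0}, {"onset_lag": -1.0}])
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.InfusionProtocol(**kwargs)

    def test_high_dose_prefix_scales_dose(self):
        p = synth.InfusionProtocol(agent="H-NE")
        assert p.agent == "NE"
        assert p.dose_scale == pytest.approx(synth.HIGH_DOSE_SCALE)
        assert p.state_name == "H-NE"

    def test_label_spans_balanced(self):
        """Rest labels span 4-109 s and infusion labels 109-214 s: 105 s each."""
        p = synth.InfusionProtocol(agent="D")
        assert p.label_change == pytest.approx(109.0)
        steps = features.step_grid(4.0, 214.0)
        labels = features._labels_for_steps(steps, p)
        rest_span = (labels == "rest").sum() * 0.1
        inf_span = (labels == "D").sum() * 0.1
        # half-open boundary puts the 109.0 s step in the infusion span
        assert rest_span == pytest.approx(105.0, abs=0.11)
        assert inf_span == pytest.approx(105.0, abs=0.11)


class TestGenerateRecording:
    def test_determinism(self):
        p = short_protocol()
        r1 = synth.generate_recording(p, _subject(4))
        r2 = synth.generate_recording(short_protocol(), _subject(4))
        assert np.array_equal(r1.ecg, r2.ecg)
        assert np.array_equal(r1.abp, r2.abp)
        assert np.array_equal(r1.truth_frame.X, r2.truth_frame.X)

    def test_record_shape_and_bounds(self, short_record):
        p = short_record.protocol
        assert short_record.ecg.size == short_record.abp.size
        assert short_record.ecg.size == int(p.timeline["end"] * short_record.fs)
        assert short_record.truth_beats["t"].max() < short_record.duration

    def test_rest_protocol_is_stationary(self):
        """No infusion => ground-truth features stay at baseline."""
        rec = synth.generate_recording(short_protocol("rest"), _subject(6, noiseless=True))
        X = rec.truth_frame.X[~rec.truth_frame.missing]
        # mean deviation from the initial value ~ 0 in every channel
        # (respiratory amplitude modulation of the pressures remains)
        drift = np.abs(X - X[0]).max(axis=0)
        assert (drift < np.maximum(5e-3 * np.abs(X[0]), 0.2)).all()
        mean_delta = np.abs(X.mean(axis=0) - X[0])
        assert (mean_delta < np.maximum(1e-3 * np.abs(X[0]), 0.05)).all()

    def test_dne_shifts_st_down_and_map_up(self):
        """Combined infusion depresses the ST epoch and raises MAP."""
        rec = synth.generate_recording(short_protocol("D+NE"), _subject(7, noiseless=True))
        fr = rec.truth_frame
        base = fr.step_times < 14.0
        inf = fr.step_times > 45.0
        assert fr.X[inf, 0].mean() < fr.X[base, 0].mean() - 0.02   # ST (mV)
        assert fr.X[inf, 10].mean() > fr.X[base, 10].mean() + 10   # MAP (mmHg)

    def test_dose_monotonicity(self):
        """|Delta| under 5x dose >= |Delta| under 1x, for every feature."""
        deltas = {}
        for dose in (1.0, 5.0):
            rec = synth.generate_recording(
                short_protocol("D+NE", dose_scale=dose), _subject(8, noiseless=True))
            fr = rec.truth_frame
            base = fr.X[fr.step_times < 14.0].mean(axis=0)
            inf = fr.X[fr.step_times > 50.0].mean(axis=0)
            deltas[dose] = np.abs(inf - base)
        assert (deltas[5.0] >= deltas[1.0] - 1e-9).all()

    def test_callback_error_aborts_with_context(self):
        def bad_hook(step, t, vec):
            raise KeyError("boom")
        with pytest.raises(RuntimeError, match="controller hook failed"):
            synth.generate_recording(short_protocol(), _subject(9), controller_hook=bad_hook)

    def test_unknown_agent_rejected(self):
        with pytest.raises(ValueError, match="unknown agent"):
            synth.InfusionProtocol(agent="X+Y")


class TestPlant:
    def test_vagotomy_makes_stimulation_inert(self):
        """With the vagus cut, stimulated and unstimulated records are
        bit-identical under the same seed."""
        plant = synth.PlantConfig(vagus_intact=False)
        assert all(g == 0.0 for g in plant.gains().values())
        always_on = lambda step, t, vec: t > 30.0
        r_stim = synth.generate_recording(short_protocol(), _subject(10), plant=plant,
                                          controller_hook=always_on)
        r_none = synth.generate_recording(short_protocol(), _subject(10), plant=plant)
        assert np.array_equal(r_stim.ecg, r_none.ecg)
        assert np.array_equal(r_stim.truth_frame.X, r_none.truth_frame.X)
        assert r_stim.stim_log    # stimulation was commanded, just inert

    def test_full_gain_relaxes_generative_values_to_baseline(self):
        plant = synth.PlantConfig(reversal_gain={f: 1.0 for f in synth.PRIMARY_FEATURES})
        on_from_40 = lambda step, t, vec: t >= 40.0
        rec = synth.generate_recording(short_protocol(), _subject(11, noiseless=True),
                                       plant=plant, controller_hook=on_from_40)
        series = rec.truth_series
        hr = series["f2"]
        t = series["t"]
        base_hr = hr[t < 14.0].mean()
        # infusion raised HR, then stimulation pulled it back to baseline
        assert hr[(t > 35) & (t < 40)].mean() > base_hr + 20
        assert abs(hr[t > 58].mean() - base_hr) < 2.0

    def test_gain_bounds_validated(self):
        with pytest.raises(ValueError):
            synth.PlantConfig(reversal_gain={"f1": 1.5})


class TestArrhythmia:
    def test_rate_zero_is_identity(self, short_record):
        assert synth.inject_arrhythmia(short_record, "PVC", 0.0) is short_record

    def test_negative_rate_rejected(self, short_record):
        with pytest.raises(ValueError):
            synth.inject_arrhythmia(short_record, "PVC", -1.0)

    @pytest.mark.parametrize("kind", ["PVC", "PAC", "VT"])
    def test_high_rate_marks_events_in_truth(self, short_record, kind):
        rec = synth.inject_arrhythmia(short_record, kind, rate=30.0, seed=3)
        kinds = rec.truth_beats["kind"]
        assert (kinds == kind).sum() >= 1
        # premature beats produce at least one short RR in truth
        rr = np.diff(rec.truth_beats["t"])
        normal_rr = np.median(rr)
        assert rr.min() < 0.75 * normal_rr

    def test_incidence_of_cohort_with_high_rate_is_total(self):
        subject = _subject(12)
        recs = []
        for i in range(5):
            base = synth.generate_recording(short_protocol(), subject)
            recs.append(synth.inject_arrhythmia(base, "PVC", rate=30.0, seed=i))
        assert synth.arrhythmia_incidence(recs) == 1.0

    def test_incidence_ordering_follows_configured_rates(self):
        """Cohorts configured with higher ectopy rates show higher incidence
        (the D+NE > D in-vivo ordering is reproduced by configuration)."""
        subject = _subject(13)
        base = synth.generate_recording(short_protocol(), subject)
        low = [synth.inject_arrhythmia(base, "PVC", rate=0.4, seed=i) for i in range(8)]
        high = [synth.inject_arrhythmia(base, "PVC", rate=20.0, seed=i) for i in range(8)]
        assert (synth.arrhythmia_incidence(high)
                > synth.arrhythmia_incidence(low) - 1e-9)


class TestCohort:
    def test_same_seed_identical(self):
        a = synth.generate_cohort(2, [short_protocol("D"), short_protocol("NE")], seed=5)
        b = synth.generate_cohort(2, [short_protocol("D"), short_protocol("NE")], seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ecg, rb.ecg)

    def test_single_rest_recording(self):
        recs = synth.generate_cohort(1, [short_protocol("rest")], seed=6)
        assert len(recs) == 1
        assert set(recs[0].labels) == {"rest"}

    def test_validation(self):
        with pytest.raises(ValueError):
            synth.generate_cohort(0, ["D"], seed=1)
        with pytest.raises(ValueError):
            synth.generate_cohort(1, [], seed=1)

    def test_ne_dne_time_series_correlate_more_than_d_ne(self, default_cohort_dataset):
        """The shared NE / D+NE effect component makes their within-subject
        feature time series correlate more strongly than D vs NE."""
        from cardioloop.workbench import state_correlations
        corr = state_correlations(default_cohort_dataset)
        assert corr["D+NE|NE"] > 0
        assert corr["D+NE|NE"] > corr["D|NE"]


class TestRecordIO:
    def test_roundtrip_csv_json(self, tmp_path, short_record):
        out = synth.save_record(short_record, tmp_path / "rec")
        loaded = synth.load_record(out)
        assert np.allclose(loaded.ecg, short_record.ecg)
        assert np.allclose(loaded.abp, short_record.abp)
        assert loaded.fs == short_record.fs
        assert loaded.protocol.agent == short_record.protocol.agent
        fr = features.extract_features(loaded)
        assert len(fr) == len(short_record.truth_frame)
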