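"""ECG chain tests: bipolar combination, filtering, resampling, detection, QC."""

import numpy as np
import pytest

from cardiomotor import (
    ECGRecording,
    EmptyTrainError,
    InvalidParameterError,
    RPeakTrain,
    bipolar_combine,
    detect_rpeaks,
    generate_rr_train,
    highpass_filter,
    orient_polarity,
    qc_rr,
    resample_to_1khz,
    synthesize_ecg,
    synthesize_three_lead,
)


def _three_channel(ch1, ch2, ch3, fs=1000.0):
    return ECGRecording(np.stack([ch1, ch2, ch3], axis=1), fs)


class TestBipolarCombine:
    def test_identical_channels_cancel(self, rng):
        x = rng.normal(size=500)
        out = bipolar_combine(_three_channel(x, x, x))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_reference_zero_passes_signal(self, rng):
        x = rng.normal(size=500)
        out = bipolar_combine(_three_channel(np.zeros(500), x, x))
        np.testing.assert_allclose(out.data, x)

    def test_constant_channels_average(self):
        out = bipolar_combine(
            _three_channel(np.zeros(100), np.full(100, 2.0), np.full(100, 4.0))
        )
        np.testing.assert_allclose(out.data, 3.0)

    def test_wrong_channel_count_raises(self):
        with pytest.raises(InvalidParameterError):
            bipolar_combine(ECGRecording(np.zeros((100, 2)), 1000.0))


class TestHighpass:
    def test_constant_input_removed(self):
        rec = ECGRecording(np.full(200_000, 5.0), 1000.0)
        out = highpass_filter(rec)
        trim = slice(5000, -5000)
        assert np.max(np.abs(out.data[trim])) < 1e-6 * 5.0

    def test_10hz_amplitude_preserved(self):
        # a 0.01 Hz filter has ~20 s transients; measure steady state only
        t = np.arange(180_000) / 1000.0
        rec = ECGRecording(np.sin(2 * np.pi * 10 * t), 1000.0)
        out = highpass_filter(rec)
        trim = slice(60_000, -60_000)
        amp = np.max(np.abs(out.data[trim]))
        assert abs(amp - 1.0) < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        rec = ECGRecording(np.zeros(1000), 1000.0)
        with pytest.raises(InvalidParameterError):
            highpass_filter(rec, cutoff=600.0)

    def test_drift_does_not_move_detected_peaks(self):
        train = generate_rr_train(60, 825, 30, seed=4)
        flat = synthesize_ecg(train, noise_sd=0.0, drift_slope=0.0)
        drifted = synthesize_ecg(train, noise_sd=0.0, drift_slope=0.001)
        t_flat = detect_rpeaks(highpass_filter(flat)).times
        t_drift = detect_rpeaks(highpass_filter(drifted)).times
        np.testing.assert_array_equal(t_flat, t_drift)


class TestResample:
    def test_identity_at_1khz(self, rng):
        rec = ECGRecording(rng.normal(size=2000), 1000.0)
        out = resample_to_1khz(rec)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_output_length_rule(self, rng):
        rec = ECGRecording(rng.normal(size=2048), 2048.0)
        out = resample_to_1khz(rec)
        assert out.n_samples == round(2048 * 1000 / 2048)
        assert out.fs == 1000.0

    def test_peaks_survive_2048hz_resampling(self):
        train = generate_rr_train(60, 825, 30, seed=9)
        rec = synthesize_ecg(train, fs=2048.0, noise_sd=0.0)
        out = resample_to_1khz(rec)
        detected = detect_rpeaks(out).times
        assert detected.size == len(train)
        assert np.max(np.abs(detected - train.times)) <= 1


class TestDetect:
    def test_noise_free_peaks_found_exactly(self):
        train = RPeakTrain(np.array([1000, 1825, 2650]))
        rec = synthesize_ecg(train, noise_sd=0.0)
        detected = detect_rpeaks(rec)
        assert detected.times.tolist() == [1000, 1825, 2650]

    def test_inverted_signal_is_rejected(self):
        train = RPeakTrain(np.array([1000, 1825, 2650]))
        rec = synthesize_ecg(train, noise_sd=0.0)
        with pytest.raises(EmptyTrainError):
            detect_rpeaks(ECGRecording(-rec.data, rec.fs, rec.t0))

    def test_orientation_step_restores_inverted_signal(self):
        train = RPeakTrain(np.array([1000, 1825, 2650]))
        rec = synthesize_ecg(train, noise_sd=0.0)
        flipped = ECGRecording(-rec.data, rec.fs, rec.t0)
        detected = detect_rpeaks(orient_polarity(flipped))
        assert detected.times.tolist() == [1000, 1825, 2650]

    def test_amplitude_scaling_invariance(self, rng):
        train = generate_rr_train(80, 825, 30, seed=13)
        rec = synthesize_ecg(train, noise_sd=0.02, seed=14)
        a = detect_rpeaks(rec).times
        b = detect_rpeaks(ECGRecording(rec.data * 7.3, rec.fs, rec.t0)).times
        np.testing.assert_array_equal(a, b)

    def test_refractory_merges_double_bumps(self):
        # two bumps 100 ms apart must yield a single detection (the larger)
        fs = 1000.0
        x = np.zeros(3000)
        k = np.arange(-10, 11)
        bump = 0.5 * (1 + np.cos(np.pi * k / 10))
        x[1000 + k] += bump
        x[1100 + k] += 0.8 * bump
        x[2000 + k] += bump
        detected = detect_rpeaks(ECGRecording(x, fs))
        assert detected.times.tolist() == [1000, 2000]

    def test_snr20_end_to_end_recovery(self):
        from cardiomotor.experiments import rpeak_recovery

        res = rpeak_recovery(n_beats=120, peak_snr=20.0, seed=5)
        assert res["sensitivity"] == 1.0
        assert res["ppv"] == 1.0
        assert res["max_abs_dt_ms"] <= 2.0

    def test_overlapping_templates_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthesize_ecg(RPeakTrain(np.array([1000, 1010])), noise_sd=0.0)

    def test_drift_linearity_of_synthesis(self):
        train = RPeakTrain(np.array([1000, 1825, 2650]))
        flat = synthesize_ecg(train, noise_sd=0.0, drift_slope=0.0)
        drifted = synthesize_ecg(train, noise_sd=0.0, drift_slope=0.001)
        t_s = np.arange(flat.n_samples) / flat.fs
        np.testing.assert_allclose(drifted.data - 0.001 * t_s, flat.data, atol=1e-12)

    def test_three_lead_combination_recovers_template(self):
        train = RPeakTrain(np.array([1000, 1825, 2650]))
        rec3 = synthesize_three_lead(train, noise_sd=0.0)
        combined = bipolar_combine(rec3)
        clean = synthesize_ecg(train, noise_sd=0.0)
        np.testing.assert_allclose(combined.data, clean.data, atol=1e-12)


class TestQC:
    def test_regular_train_has_no_flags(self, regular_train):
        report = qc_rr(regular_train)
        assert report.flagged_intervals == []
        assert report.mean_rr == pytest.approx(825.0)

    def test_mean_rr_identity_without_flags(self, long_train):
        report = qc_rr(long_train)
        t = long_train.times
        expected = (t[-1] - t[0]) / (t.size - 1)
        assert report.mean_rr == pytest.approx(expected)

    def test_missed_beat_interval_flagged(self):
        times = np.arange(0, 825 * 30, 825).astype(np.int64)
        times = np.delete(times, 15)  # drop one beat -> a 1650 ms interval
        report = qc_rr(RPeakTrain(times))
        assert len(report.flagged_intervals) == 1
        idx, interval, reason = report.flagged_intervals[0]
        assert interval == 1650
        assert reason == "local_outlier"

    def test_short_interval_flagged_below_bound(self):
        times = np.cumsum([0] + [825] * 10 + [250] + [825] * 10).astype(np.int64)
        report = qc_rr(RPeakTrain(times))
        reasons = {r for _, _, r in report.flagged_intervals}
        assert "below_min" in reasons
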