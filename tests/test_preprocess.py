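"""Filtering chain, Pan-Tompkins detection, ectopic correction."""
import numpy as np
import pytest

import hrvaffect as hv
from hrvaffect.preprocess import correct_ectopics

from conftest import constant_model


def sine_record(freq, fs=256.0, duration=120.0, amp=1.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return hv.ECGRecord(amp * np.sin(2 * np.pi * freq * t), fs=fs)


def central_rms(record, skip_s=30.0):
    i = int(skip_s * record.fs)
    return float(np.sqrt(np.mean(record.samples[i:-i] ** 2)))


def butterworth_hp_gain(f, fc=0.5, order=5):
    """Closed-form single-pass Butterworth high-pass magnitude."""
    return 1.0 / np.sqrt(1.0 + (fc / f) ** (2 * order))


class TestResample:
    def test_sample_count(self):
        rec = hv.ECGRecord(np.zeros(5120), fs=512.0)
        out = hv.resample(rec, 256.0)
        assert out.fs == 256.0
        assert out.n_samples == 2560

    def test_sinusoid_matches_analytic(self):
        fs_in = 1000.0
        t = np.arange(0.0, 10.0, 1.0 / fs_in)
        rec = hv.ECGRecord(np.sin(2 * np.pi * 10.0 * t), fs=fs_in)
        out = hv.resample(rec, 256.0)
        t_new = np.arange(out.n_samples) / 256.0
        expected = np.sin(2 * np.pi * 10.0 * t_new)
        mid = slice(256, -256)  # polyphase edges excluded
        assert np.max(np.abs(out.samples[mid] - expected[mid])) < 0.01

    def test_passthrough_at_target_rate(self):
        rec = hv.ECGRecord(np.random.default_rng(0).normal(size=512), fs=256.0)
        out = hv.resample(rec, 256.0)
        assert out is rec

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hv.resample(hv.ECGRecord(np.array([]), fs=256.0), 256.0)


class TestHighpass:
    def test_dc_removal(self):
        rec = hv.ECGRecord(np.full(2560, 5.0), fs=256.0)
        out = hv.highpass(rec)
        assert abs(float(np.mean(out.samples))) < 0.05  # within 1% of offset

    def test_stopband_attenuation_matches_butterworth(self):
        out = hv.highpass(sine_record(0.2, duration=240.0))
        # forward-backward pass squares the magnitude response
        bound = butterworth_hp_gain(0.2) ** 2
        assert central_rms(out, 60.0) / (1 / np.sqrt(2)) <= bound * 1.5

    def test_passband_preserved(self):
        out = hv.highpass(sine_record(20.0))
        assert central_rms(out) == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2560)
        rec = hv.ECGRecord(x, fs=256.0)
        scaled = hv.ECGRecord(3.7 * x, fs=256.0)
        assert np.allclose(hv.highpass(scaled).samples,
                           3.7 * hv.highpass(rec).samples, atol=1e-9)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            hv.highpass(hv.ECGRecord(np.zeros(512), fs=0.9))


class TestNotch:
    def test_mains_attenuated(self):
        out = hv.notch(sine_record(50.0))
        assert central_rms(out) <= 0.1 * (1 / np.sqrt(2))

    def test_passband_preserved(self):
        out = hv.notch(sine_record(10.0))
        assert central_rms(out) == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_zero_in_zero_out(self):
        out = hv.notch(hv.ECGRecord(np.zeros(2560), fs=256.0))
        assert np.allclose(out.samples, 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            hv.notch(hv.ECGRecord(np.zeros(512), fs=90.0))


def synth_subject(bpm, duration=60.0, noise=None, seed=0):
    """Clean or noisy synthetic ECG with known beat times (>=0.5 s from edges)."""
    period = 60.0 / bpm
    times = np.arange(0.5, duration, period)
    beats = hv.BeatSeries(times)
    ecg = hv.synthesize_ecg(beats, fs=256.0,
                            noise=noise or hv.NoiseSpec.clean(), seed=seed)
    return beats, ecg


def match_stats(truth, detected, tol_ms=10.0):
    """(sensitivity, positive predictivity) with one-to-one matching."""
    t, d = truth.r_times, detected.r_times
    used = np.zeros(d.size, dtype=bool)
    tp = 0
    for bt in t:
        err = np.abs(d - bt) * 1000.0
        err[used] = np.inf
        j = int(np.argmin(err))
        if err[j] <= tol_ms:
            used[j] = True
            tp += 1
    return tp / t.size, tp / d.size


class TestPanTompkins:
    def test_clean_ecg_perfect_detection(self):
        beats, ecg = synth_subject(80.0)
        detected = hv.detect_r_peaks(ecg)
        se, ppv = match_stats(beats, detected)
        assert se == 1.0 and ppv == 1.0

    @pytest.mark.parametrize("bpm", [50, 65, 80, 100, 120])
    def test_rate_sweep_beat_count(self, bpm):
        beats, ecg = synth_subject(bpm)
        detected = hv.detect_r_peaks(ecg)
        assert abs(detected.n_beats - beats.n_beats) <= 1

    @pytest.mark.parametrize("bpm", [55, 75, 110])
    def test_moderate_noise_sensitivity(self, bpm):
        noise = hv.NoiseSpec(wander_amp=0.1, mains_amp=0.05, white_sd=0.05)
        beats, ecg = synth_subject(bpm, noise=noise, seed=42)
        rec = hv.notch(hv.highpass(ecg))
        detected = hv.detect_r_peaks(rec)
        se, ppv = match_stats(beats, detected)
        assert se >= 0.99 and ppv >= 0.99

    def test_flat_line_rejected(self):
        rec = hv.ECGRecord(np.zeros(256 * 30), fs=256.0)
        with pytest.raises(hv.DetectionError):
            hv.detect_r_peaks(rec)

    def test_short_record_rejected(self):
        rec = hv.ECGRecord(np.zeros(256 * 3), fs=256.0)
        with pytest.raises(hv.DetectionError, match="short"):
            hv.detect_r_peaks(rec)


class TestCorrectEctopics:
    def test_regular_series_untouched(self, regular_beats):
        out = correct_ectopics(regular_beats)
        assert out is regular_beats

    @pytest.mark.parametrize("fraction", [0.05, 0.10])
    def test_injected_ectopics_flagged_and_corrected(self, regular_beats, fraction):
        inj = hv.inject_ectopics(regular_beats, fraction, seed=9)
        out = correct_ectopics(inj)
        truth = {i for i, a in enumerate(inj.annotations) if a == "ectopic"}
        flagged = {i for i, a in enumerate(out.annotations) if a == "interpolated"}
        assert truth <= flagged
        assert np.all(np.abs(out.rr - 1000.0) <= 50.0)  # within 5% of truth

    def test_beat_count_and_unflagged_times_preserved(self, regular_beats):
        inj = hv.inject_ectopics(regular_beats, 0.08, seed=2)
        out = correct_ectopics(inj)
        assert out.n_beats == inj.n_beats
        keep = [i for i, a in enumerate(out.annotations) if a != "interpolated"]
        assert np.array_equal(out.r_times[keep], inj.r_times[keep])

    def test_twenty_percent_rule(self, regular_beats):
        inj = hv.inject_ectopics(regular_beats, 0.25, seed=7)
        with pytest.raises(hv.UncorrectableSeriesError) as err:
            correct_ectopics(inj)
        assert err.value.fraction >= 0.20

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            correct_ectopics(hv.BeatSeries(np.arange(5.0)))


class TestEndToEnd:
    def test_window_mean_rr_recovered(self, default_protocol):
        """generate -> synthesize -> filter -> detect -> correct recovers the
        window-mean R-R within 2 ms of generator truth at default noise."""
        model = constant_model(m0=800.0, acquaintance=40.0, stranger=0.0)
        truth = hv.generate_beats(default_protocol, model, seed=6)
        # limit to the first stimulus/rest pair to keep the record short
        end = default_protocol.events[2].end
        sub = hv.BeatSeries(truth.r_times[(truth.r_times > 0.5)
                                          & (truth.r_times < end)])
        ecg = hv.synthesize_ecg(sub, fs=256.0, noise=hv.NoiseSpec(), seed=6)
        rec = hv.notch(hv.highpass(hv.resample(ecg, 256.0)))
        beats = correct_ectopics(hv.detect_r_peaks(rec))
        for event in default_protocol.events[1:3]:
            sel_t = beats.r_times[1:]
            sel_s = sub.r_times[1:]
            got = beats.rr[(sel_t >= event.onset) & (sel_t < event.end)].mean()
            want = sub.rr[(sel_s >= event.onset) & (sel_s < event.end)].mean()
            assert abs(got - want) < 2.0
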