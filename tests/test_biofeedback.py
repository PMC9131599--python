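"""Causal envelope, threshold calibration, beep events, overlap, audio."""

import numpy as np
import pytest

from pedalemg import (calibrate_threshold, causal_envelope, detect_beep_events,
                      overlap_metrics, render_audio)
from pedalemg.biofeedback import BeepEventLog, ThresholdCalibration
from pedalemg.processing import EnvelopeTrace


def _env(values, fs=1000.0):
    return EnvelopeTrace(fs_hz=fs, values=np.asarray(values, float))


def _calib(threshold, muscle="VL"):
    return ThresholdCalibration(muscle=muscle, rest_amplitude=0.0,
                                pedaling_max=max(threshold * 2, 1.0),
                                threshold=threshold)


class TestCausalEnvelope:
    def test_zero_input_gives_zero_output(self):
        env = causal_envelope(np.zeros(500))
        assert np.all(env.values == 0.0)

    def test_step_response_respects_causality_and_window(self):
        x = np.r_[np.zeros(300), np.ones(500)]
        env = causal_envelope(x, window_ms=100.0)
        assert np.all(env.values[:300] == 0.0)  # nothing before the step
        assert env.values[300] < 0.99
        assert np.all(env.values[300 + 100:] >= 0.99)  # settled within window

    def test_constant_input_reaches_steady_state_value(self):
        env = causal_envelope(np.full(400, 2.5), window_ms=50.0)
        np.testing.assert_allclose(env.values[60:], 2.5, rtol=1e-12)

    def test_window_longer_than_recording_is_rejected(self):
        with pytest.raises(ValueError, match="window"):
            causal_envelope(np.zeros(50), window_ms=100.0)

    def test_future_samples_never_affect_past_output(self, rng):
        x = rng.normal(size=1000)
        y = x.copy()
        y[600:] += rng.normal(size=400) * 5
        a = causal_envelope(x).values
        b = causal_envelope(y).values
        np.testing.assert_array_equal(a[:600], b[:600])
        assert not np.allclose(a[600:], b[600:])


class TestCalibrateThreshold:
    def test_five_percent_rule_from_zero_rest(self):
        c = calibrate_threshold(_env(np.zeros(100) + 0.0), _env([0.2, 1.0]))
        assert c.threshold == pytest.approx(0.05)

    def test_five_percent_rule_above_rest_level(self):
        c = calibrate_threshold(_env(np.full(100, 0.1)), _env([0.5, 2.1]))
        assert c.threshold == pytest.approx(0.2)  # 0.1 + 0.05 * 2.0
        assert c.rest_amplitude == pytest.approx(0.1)
        assert c.pedaling_max == pytest.approx(2.1)

    def test_absolute_rule_ignores_rest(self):
        c = calibrate_threshold(_env(np.full(100, 0.01)), _env([0.5, 2.0]),
                                rule="absolute")
        assert c.threshold == pytest.approx(0.1)

    def test_rest_equal_to_max_is_uncalibratable(self):
        with pytest.raises(ValueError, match="uncalibratable"):
            calibrate_threshold(_env(np.full(10, 1.0)), _env(np.full(10, 1.0)))


class TestDetectBeepEvents:
    def test_always_below_threshold_gives_no_events(self):
        log = detect_beep_events(_env(np.full(1000, 0.1)), _calib(0.5))
        assert log.events == []

    def test_always_above_threshold_gives_one_full_span_event(self):
        log = detect_beep_events(_env(np.full(1000, 0.9)), _calib(0.5))
        assert len(log.events) == 1
        onset, offset = log.events[0]
        assert onset == 0.0
        assert offset == pytest.approx(1.0)

    def test_rectangular_pulse_onset_offset_within_one_sample(self):
        v = np.zeros(2000)
        v[500:1200] = 1.0
        log = detect_beep_events(_env(v), _calib(0.5), debounce_ms=0.0)
        assert len(log.events) == 1
        onset, offset = log.events[0]
        assert onset == pytest.approx(0.5, abs=1e-3)
        assert offset == pytest.approx(1.2, abs=1e-3)

    def test_debounce_drops_chatter_and_bridges_short_gaps(self):
        v = np.zeros(2000)
        v[100:110] = 1.0           # 10 ms blip: dropped
        v[500:700] = 1.0
        v[720:900] = 1.0           # 20 ms gap: bridged
        log = detect_beep_events(_env(v), _calib(0.5), debounce_ms=50.0)
        assert len(log.events) == 1
        onset, offset = log.events[0]
        assert onset == pytest.approx(0.5, abs=1e-3)
        assert offset == pytest.approx(0.9, abs=1e-3)

    def test_beep_on_time_is_non_increasing_in_threshold(self, rng):
        v = np.abs(np.convolve(rng.normal(size=5000), np.ones(50) / 50,
                               mode="same"))
        for debounce in (0.0, 50.0):
            totals = []
            for thr in np.quantile(v, [0.2, 0.4, 0.6, 0.8]):
                log = detect_beep_events(_env(v), _calib(float(thr)),
                                         debounce_ms=debounce)
                totals.append(log.total_on_s)
            assert np.all(np.diff(totals) <= 1e-12)

    def test_default_pitch_follows_the_muscle(self):
        log = detect_beep_events(_env(np.full(100, 1.0)), _calib(0.5, "ST"))
        assert log.freq_hz == 800.0


class TestOverlapMetrics:
    def _log(self, events, muscle="VL", freq=400.0):
        return BeepEventLog(muscle=muscle, freq_hz=freq, events=events)

    def test_disjoint_event_sets_have_zero_overlap(self):
        s, f = overlap_metrics(self._log([(0.0, 1.0)]),
                               self._log([(2.0, 3.0)], "ST", 800.0))
        assert (s, f) == (0.0, 0.0)

    def test_identical_event_sets_fully_overlap(self):
        ev = [(0.0, 1.0), (2.0, 2.5)]
        s, f = overlap_metrics(self._log(ev), self._log(ev, "ST", 800.0))
        assert s == pytest.approx(1.5)
        assert f == pytest.approx(1.0)

    def test_partial_overlap_hand_example(self):
        s, f = overlap_metrics(self._log([(0.0, 2.0)]),
                               self._log([(1.0, 3.0)], "ST", 800.0))
        assert s == pytest.approx(1.0)
        assert f == pytest.approx(0.5)

    def test_empty_log_gives_zero(self):
        s, f = overlap_metrics(self._log([]), self._log([(0.0, 1.0)]))
        assert (s, f) == (0.0, 0.0)

    def test_matches_millisecond_grid_brute_force(self, rng):
        for _ in range(20):
            def random_log(muscle, freq):
                edges = np.sort(rng.uniform(0.0, 10.0, size=8)).round(3)
                ev = [(edges[i], edges[i + 1]) for i in range(0, 8, 2)
                      if edges[i + 1] > edges[i]]
                return self._log(ev, muscle, freq)
            a = random_log("VL", 400.0)
            b = random_log("ST", 800.0)
            grid = np.arange(0, 10_000) / 1000.0 + 0.0005  # bin centers
            on_a = np.zeros(grid.size, bool)
            on_b = np.zeros(grid.size, bool)
            for x0, x1 in a.events:
                on_a |= (grid >= x0) & (grid < x1)
            for x0, x1 in b.events:
                on_b |= (grid >= x0) & (grid < x1)
            brute = (on_a & on_b).sum() / 1000.0
            s, _ = overlap_metrics(a, b)
            assert s == pytest.approx(brute, abs=2e-3 * max(len(a.events),
                                                            len(b.events)))


class TestRenderAudio:
    def _peak_freq(self, audio, fs):
        spec = np.abs(np.fft.rfft(audio))
        return np.fft.rfftfreq(audio.size, 1.0 / fs)[spec.argmax()]

    def test_empty_logs_render_silence(self):
        audio = render_audio([BeepEventLog("VL", 400.0, [])],
                             duration_s=0.5)
        assert np.all(audio == 0.0)

    def test_single_tone_has_spectral_peak_at_its_pitch(self):
        fs = 44100.0
        log = BeepEventLog("VL", 400.0, [(0.1, 0.9)])
        audio = render_audio([log], audio_fs_hz=fs, duration_s=1.0)
        seg = audio[int(0.2 * fs):int(0.8 * fs)]
        bin_hz = fs / seg.size
        assert abs(self._peak_freq(seg, fs) - 400.0) <= bin_hz
        assert np.abs(audio).max() == pytest.approx(0.9, rel=1e-6)

    def test_simultaneous_tones_show_both_spectral_peaks(self):
        fs = 44100.0
        logs = [BeepEventLog("VL", 400.0, [(0.0, 1.0)]),
                BeepEventLog("ST", 800.0, [(0.0, 1.0)])]
        audio = render_audio(logs, audio_fs_hz=fs, duration_s=1.0)
        spec = np.abs(np.fft.rfft(audio))
        freqs = np.fft.rfftfreq(audio.size, 1.0 / fs)
        for f0 in (400.0, 800.0):
            band = spec[np.abs(freqs - f0) <= 2.0]
            assert band.max() > 0.2 * spec.max()

    def test_event_beyond_duration_is_rejected(self):
        log = BeepEventLog("VL", 400.0, [(0.0, 2.0)])
        with pytest.raises(ValueError, match="beyond"):
            render_audio([log], duration_s=1.0)

    def test_round_trip_event_recovery_within_15_ms(self):
        fs = 8000.0
        events = [(0.20, 0.60), (1.00, 1.35)]
        log = BeepEventLog("VL", 400.0, events)
        audio = render_audio([log], audio_fs_hz=fs, duration_s=1.6)
        env = causal_envelope(np.abs(audio), fs_hz=fs, window_ms=5.0,
                              weights="uniform")
        calib = _calib(0.3 * env.values.max())
        rec = detect_beep_events(env, calib, debounce_ms=20.0)
        assert len(rec.events) == len(events)
        for (t0, t1), (r0, r1) in zip(events, rec.events):
            assert abs(r0 - t0) <= 0.015
            assert abs(r1 - t1) <= 0.015
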