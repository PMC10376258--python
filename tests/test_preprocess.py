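"""Band-pass, Hampel, RMS normalization and burst detection."""

import numpy as np
import pytest
from scipy import signal as sps

import emgsnail as es


def _sine(freq, fs=1000.0, seconds=2.0, channels=1):
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return es.Recording(
        samples=np.tile(x[:, None], (1, channels)), fs=fs, subject_id="S",
        channel_roles=("flexor",) * channels,
    )


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = _sine(100.0)
        out = es.bandpass(rec)
        mid = slice(200, -200)  # skip edge transients
        ratio = np.max(np.abs(out.samples[mid])) / np.max(np.abs(rec.samples[mid]))
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuation_matches_designed_response(self):
        """5 Hz suppression agrees with the filter's own frequency response
        and exceeds 20 dB."""
        spec = es.FilterSpec()
        rec = _sine(5.0, seconds=8.0)
        out = es.bandpass(rec, spec)
        mid = slice(1000, -1000)
        power_ratio = np.mean(out.samples[mid] ** 2) / np.mean(rec.samples[mid] ** 2)
        sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[5.0], fs=rec.fs)
        expected = np.abs(h[0]) ** 4  # forward-backward squares the response
        assert power_ratio < 10 ** (-20 / 10)
        assert power_ratio == pytest.approx(expected, rel=0.2)

    def test_dc_killed(self):
        rec = es.Recording(samples=np.full((4000, 1), 3.0), fs=1000.0,
                           subject_id="S", channel_roles=("flexor",))
        out = es.bandpass(rec)
        assert np.max(np.abs(out.samples[500:-500])) < 1e-6 * 3.0

    def test_linearity(self, rng):
        x = rng.standard_normal((2000, 2))
        rec = es.Recording(samples=x, fs=1000.0, subject_id="S",
                           channel_roles=("flexor", "extensor"))
        scaled = es.bandpass(rec.with_samples(3.5 * x))
        np.testing.assert_allclose(scaled.samples,
                                   3.5 * es.bandpass(rec).samples, atol=1e-9)

    def test_length_preserved(self, rng):
        rec = es.Recording(samples=rng.standard_normal((1234, 1)), fs=1000.0,
                           subject_id="S", channel_roles=("flexor",))
        assert es.bandpass(rec).n_samples == 1234

    def test_band_above_nyquist_rejected(self):
        rec = _sine(100.0, fs=500.0)
        with pytest.raises(es.ConfigurationError):
            es.bandpass(rec, es.FilterSpec(band=(20.0, 300.0)))


class TestHampel:
    def test_clean_sinusoid_unchanged(self):
        rec = _sine(50.0)
        out = es.hampel(rec)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_spike_replaced_locally(self):
        rec = _sine(50.0)
        spec = es.FilterSpec()
        spiked = rec.samples.copy()
        spiked[1000, 0] += 10.0
        out = es.hampel(rec.with_samples(spiked), spec)
        assert abs(out.samples[1000, 0]) < 2.0  # spike removed
        far = np.r_[0:1000 - spec.hampel_window, 1000 + spec.hampel_window:2000]
        np.testing.assert_array_equal(out.samples[far, 0], spiked[far, 0])

    def test_constant_with_spike(self):
        x = np.full((500, 1), 2.0)
        x[250, 0] = 50.0
        rec = es.Recording(samples=x, fs=1000.0, subject_id="S",
                           channel_roles=("flexor",))
        out = es.hampel(rec)
        np.testing.assert_array_equal(out.samples, np.full((500, 1), 2.0))

    def test_changes_at_most_injected_spikes(self, rng):
        rec = _sine(50.0)
        spiked = rec.samples.copy()
        spots = rng.choice(np.arange(100, 1900), size=5, replace=False)
        spiked[spots, 0] += 15.0
        out = es.hampel(rec.with_samples(spiked))
        assert np.count_nonzero(out.samples != spiked) <= 5


class TestRmsNormalize:
    def test_target_rms_reached(self):
        rec = es.Recording(samples=np.array([[3.0], [4.0], [0.0], [0.0]]),
                           fs=1000.0, subject_id="S", channel_roles=("flexor",))
        out = es.rms_normalize(rec, 1.0)
        assert np.sqrt(np.mean(out.samples ** 2)) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_unit_rms(self, rng):
        x = rng.standard_normal((1000, 1))
        x /= np.sqrt(np.mean(x ** 2))
        rec = es.Recording(samples=x, fs=1000.0, subject_id="S",
                           channel_roles=("flexor",))
        np.testing.assert_allclose(es.rms_normalize(rec).samples, x, atol=1e-12)

    def test_channels_equalized(self, rng):
        x = rng.standard_normal((1000, 2)) * np.array([1.0, 50.0])
        rec = es.Recording(samples=x, fs=1000.0, subject_id="S",
                           channel_roles=("flexor", "extensor"))
        out = es.rms_normalize(rec, 2.0)
        rms = np.sqrt(np.mean(out.samples ** 2, axis=0))
        np.testing.assert_allclose(rms, 2.0, atol=1e-12)

    def test_zero_channel_named(self):
        x = np.zeros((100, 2))
        x[:, 0] = 1.0
        rec = es.Recording(samples=x, fs=1000.0, subject_id="S",
                           channel_roles=("flexor", "extensor"))
        with pytest.raises(es.DegenerateSignalError, match=r"\[1\]"):
            es.rms_normalize(rec)


class TestDetectGestures:
    def test_flat_signal_yields_nothing(self, rng):
        rec = es.Recording(samples=1e-6 * rng.standard_normal((4000, 1)),
                           fs=1000.0, subject_id="S", channel_roles=("flexor",))
        assert es.detect_gestures(rec) == []

    def test_single_burst_single_window(self):
        cfg = es.SynthConfig(n_subjects=1, reps_per_gesture=1, seed=4,
                             subject_gain_sd=0.0, crosstalk=0.0)
        ds = es.generate_dataset(cfg)
        rec = es.preprocess_pipeline(ds.recordings[0])
        # keep only the span around the first annotated burst
        ann = ds.annotations[0]
        lo = max(0, ann["onset"] - 400)
        hi = min(rec.n_samples, ann["onset"] + ann["duration"] + 400)
        sub = rec.with_samples(rec.samples[lo:hi])
        windows = es.detect_gestures(sub)
        assert len(windows) == 1
        start = windows[0].onset_index
        end = start + windows[0].window.shape[0]
        peak = (ann["onset"] - lo) + ann["duration"] // 2
        assert start <= peak <= end + 200  # window locks onto the burst region

    def test_windows_ordered_by_onset(self, separable_dataset):
        rec = es.preprocess_pipeline(separable_dataset.recordings[0])
        windows = es.detect_gestures(rec)
        onsets = [w.onset_index for w in windows]
        assert onsets == sorted(onsets)
        assert len(windows) >= 2

    def test_window_lengths_clamped(self, separable_dataset):
        spec = es.DetectionSpec()
        rec = es.preprocess_pipeline(separable_dataset.recordings[0])
        for w in es.detect_gestures(rec, spec):
            ms = 1000.0 * w.window.shape[0] / rec.fs
            assert spec.min_window_ms <= ms <= spec.max_window_ms

    def test_recall_and_precision_on_ground_truth(self):
        """At severity 1 without artifacts, detection recovers >= 95% of
        annotated bursts and >= 95% of windows land inside a burst."""
        recalls, precisions = [], []
        for seed in range(5):
            cfg = es.SynthConfig(n_subjects=2, reps_per_gesture=5, seed=seed,
                                 severity=1.0, artifact_rate=0.0)
            ds = es.generate_dataset(cfg)
            for rec in ds.recordings:
                cleaned = es.preprocess_pipeline(rec)
                windows = es.detect_gestures(cleaned)
                anns = ds.annotations_for(rec.subject_id)
                hit_bursts = set()
                in_burst = 0
                for w in windows:
                    mid = w.onset_index + w.window.shape[0] // 2
                    for k, a in enumerate(anns):
                        if a["onset"] <= mid <= a["onset"] + a["duration"]:
                            hit_bursts.add(k)
                            in_burst += 1
                            break
                recalls.append(len(hit_bursts) / len(anns))
                precisions.append(in_burst / max(len(windows), 1))
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_too_short_recording_rejected(self, rng):
        rec = es.Recording(samples=rng.standard_normal((50, 1)), fs=1000.0,
                           subject_id="S", channel_roles=("flexor",))
        with pytest.raises(es.DegenerateSignalError):
            es.detect_gestures(rec)


class TestPipeline:
    def test_fixed_order_and_unit_rms(self, separable_dataset):
        rec = separable_dataset.recordings[0]
        cleaned = es.preprocess_pipeline(rec)
        rms = np.sqrt(np.mean(cleaned.samples ** 2, axis=0))
        np.testing.assert_allclose(rms, 1.0, atol=1e-9)

    def test_pipeline_with_detection(self, separable_dataset):
        rec = separable_dataset.recordings[0]
        cleaned, segments = es.preprocess_pipeline(
            rec, detection_spec=es.DetectionSpec()
        )
        assert segments and all(s.subject_id == rec.subject_id for s in segments)
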