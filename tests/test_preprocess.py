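"""Resampling, filtering, artifact masking, windowing, standardization."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ictalert.preprocess import (
    NormStats,
    Recording,
    compute_norm_stats,
    filter_eeg,
    reject_artifacts,
    resample,
    segment,
    standardize,
)

RNG = np.random.default_rng(0)


def sine_recording(freq: float, fs: float, dur: float = 1.0, amp: float = 50.0) -> Recording:
    t = np.arange(int(dur * fs)) / fs
    return Recording(signal=amp * np.sin(2 * np.pi * freq * t)[None, :], fs=fs)


class TestResample:
    @pytest.mark.parametrize("fs,n,expected", [(2500.0, 2500, 256), (256.0, 2560, 2560)])
    def test_output_length(self, fs, n, expected):
        rec = Recording(signal=RNG.normal(size=(2, n)), fs=fs)
        assert resample(rec, 256.0).n_samples == expected

    def test_identity_at_target_rate(self):
        rec = Recording(signal=RNG.normal(size=(1, 512)), fs=256.0)
        out = resample(rec, 256.0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_sine_survives_resampling(self):
        """FFT oracle: a 10 Hz tone keeps its frequency and amplitude."""
        rec = sine_recording(10.0, 2500.0, dur=4.0)
        out = resample(rec, 256.0)
        spec = np.abs(np.fft.rfft(out.signal[0] * np.hanning(out.n_samples)))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 256.0)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 10.0) < 0.3
        mid = out.signal[0, out.n_samples // 4 : -out.n_samples // 4]
        assert abs(mid.max() - 50.0) / 50.0 < 0.01

    def test_mask_follows_resampling(self):
        mask = np.ones(2500, dtype=bool)
        mask[1000:1500] = False
        rec = Recording(signal=RNG.normal(size=(1, 2500)), fs=2500.0, valid_mask=mask)
        out = resample(rec, 256.0)
        assert not out.valid_mask[105:150].any()
        assert out.valid_mask[:100].all()


class TestFilter:
    def test_dc_offset_removed(self):
        rec = Recording(signal=np.full((1, 2560), 100.0), fs=256.0)
        out = filter_eeg(rec)
        assert abs(out.signal.mean()) < 0.1

    def test_notch_attenuates_mains(self):
        """FFT oracle: >= 20 dB attenuation at 50 Hz (edge transients of the
        zero-phase filter excluded)."""
        rec = sine_recording(50.0, 256.0, dur=8.0)
        out = filter_eeg(rec)
        core = slice(512, -512)
        ratio = np.sqrt(np.mean(out.signal[0, core] ** 2) / np.mean(rec.signal[0, core] ** 2))
        assert 20 * np.log10(1 / ratio) >= 20.0

    def test_out_of_band_power_suppressed(self):
        """Periodogram oracle: filtered white noise keeps < 5% of its power
        outside the pass band."""
        rec = Recording(signal=RNG.normal(size=(1, 256 * 30)), fs=256.0)
        out = filter_eeg(rec, band=(0.5, 100.0))
        f, P = periodogram(out.signal[0], fs=256.0)
        out_band = P[(f < 0.4) | (f > 110.0)].sum()
        assert out_band / P.sum() < 0.05

    def test_invalid_band_rejected(self):
        rec = Recording(signal=RNG.normal(size=(1, 256)), fs=256.0)
        with pytest.raises(ValueError):
            filter_eeg(rec, band=(100.0, 0.5))

    def test_filtering_idempotent_on_passband_content(self):
        """A second filter pass leaves in-band content essentially unchanged
        (< 1%); only transition-band energy is re-attenuated."""
        t = np.arange(256 * 20) / 256.0
        sig = 30 * np.sin(2 * np.pi * 10 * t) + 20 * np.sin(2 * np.pi * 22 * t)
        once = filter_eeg(Recording(signal=sig[None, :], fs=256.0))
        twice = filter_eeg(once)
        core = slice(512, -512)  # ignore edge transients
        rel = np.linalg.norm(twice.signal[0, core] - once.signal[0, core]) / np.linalg.norm(
            once.signal[0, core]
        )
        assert rel < 0.01


class TestArtifacts:
    def test_clean_signal_unchanged(self):
        rec = Recording(signal=RNG.normal(size=(2, 2560)) * 10, fs=256.0)
        out = reject_artifacts(rec, amp_thresh=300.0)
        assert out.valid_mask.all()

    def test_spike_neighbourhood_masked(self):
        sig = RNG.normal(size=(1, 2560)) * 10
        sig[0, 1000] = 500.0
        out = reject_artifacts(Recording(signal=sig, fs=256.0), amp_thresh=300.0)
        pad = int(0.1 * 256)
        assert not out.valid_mask[1000 - pad : 1000 + pad].any()
        assert out.valid_mask[:900].all()
        np.testing.assert_array_equal(out.signal, sig)  # values untouched

    def test_masked_fraction_tracks_injected_artifacts(self):
        """Generator ground truth: masked time within 2x of the injected
        artifact duration (0.3 s per event plus 0.1 s padding each side)."""
        from ictalert.synthetic import SimSpec, generate_recording

        ds = generate_recording(
            SimSpec(duration=3600.0, n_channels=2, artifact_rate=12.0, seed=13)
        )
        out = reject_artifacts(ds.recording, amp_thresh=300.0)
        masked_s = (~out.valid_mask).sum() / 256.0
        injected_s = sum(d for _, d in ds.artifact_events) + 0.2 * len(ds.artifact_events)
        assert len(ds.artifact_events) > 0
        assert masked_s <= 2.0 * injected_s
        assert masked_s >= 0.3 * injected_s


class TestSegment:
    def test_full_hour(self):
        rec = Recording(signal=np.zeros((1, 256 * 3600)), fs=256.0)
        ws = segment(rec)
        assert len(ws) == 360 and ws.valid.all()

    def test_trailing_partial_window_dropped(self):
        rec = Recording(signal=np.zeros((1, 256 * 25)), fs=256.0)
        assert len(segment(rec)) == 2

    def test_short_recording_empty(self):
        assert len(segment(Recording(signal=np.zeros((1, 256 * 9)), fs=256.0))) == 0

    def test_invalid_span_invalidates_overlapping_windows(self):
        mask = np.ones(256 * 3600, dtype=bool)
        mask[95 * 256 : 105 * 256] = False
        rec = Recording(signal=np.zeros((1, 256 * 3600)), fs=256.0, valid_mask=mask)
        ws = segment(rec)  # 100% valid rule
        assert not ws.valid[9] and not ws.valid[10]
        assert ws.valid[8] and ws.valid[11]

    def test_relaxed_valid_fraction(self):
        mask = np.ones(256 * 20, dtype=bool)
        mask[: 256 * 2] = False  # 20% of the first window
        rec = Recording(signal=np.zeros((1, 256 * 20)), fs=256.0, valid_mask=mask)
        assert not segment(rec).valid[0]
        assert segment(rec, min_valid_frac=0.7).valid[0]


class TestStandardize:
    def _windows(self, sig: np.ndarray):
        return segment(Recording(signal=sig, fs=256.0))

    def test_flat_channel_sd_floored(self):
        ws = self._windows(np.zeros((1, 2560 * 4)))
        with pytest.warns(UserWarning, match="floored"):
            stats = compute_norm_stats(ws)
        assert stats.sd[0] == pytest.approx(1e-6)

    def test_large_sample_statistics(self):
        """Monte-Carlo: standard-normal input gives mean ~ 0, sd ~ 1."""
        ws = self._windows(RNG.standard_normal((2, 2560 * 1000)))
        stats = compute_norm_stats(ws)
        np.testing.assert_allclose(stats.mean, 0.0, atol=0.01)
        np.testing.assert_allclose(stats.sd, 1.0, atol=0.01)

    def test_self_standardization_is_unit(self):
        ws = self._windows(RNG.normal(5.0, 3.0, size=(2, 2560 * 50)))
        out = standardize(ws, compute_norm_stats(ws))
        assert abs(out.windows.mean()) < 1e-3
        np.testing.assert_allclose(out.windows.std(axis=(0, 2)), 1.0, atol=1e-3)

    def test_identity_and_roundtrip(self):
        ws = self._windows(RNG.normal(size=(1, 2560 * 3)))
        ident = standardize(ws, NormStats(mean=np.zeros(1), sd=np.ones(1)))
        np.testing.assert_allclose(ident.windows, ws.windows, atol=1e-7)
        stats = NormStats(mean=np.array([2.0]), sd=np.array([4.0]))
        back = standardize(ws, stats).windows * 4.0 + 2.0
        np.testing.assert_allclose(back, ws.windows, atol=1e-5)

    def test_channel_mismatch_rejected(self):
        ws = self._windows(RNG.normal(size=(2, 2560 * 2)))
        with pytest.raises(ValueError, match="channel"):
            standardize(ws, NormStats(mean=np.zeros(3), sd=np.ones(3)))

    def test_segment_standardize_commute(self):
        sig = RNG.normal(3.0, 2.0, size=(2, 2560 * 5)).astype(np.float32)
        stats = NormStats(mean=np.array([3.0, 3.0]), sd=np.array([2.0, 2.0]))
        a = standardize(self._windows(sig), stats).windows
        sig_std = (sig - np.array([[3.0], [3.0]], dtype=np.float32)) / 2.0
        b = self._windows(sig_std).windows
        np.testing.assert_allclose(a, b, atol=1e-6)
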