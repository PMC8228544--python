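"""Codec: duration arithmetic, frequency map, sonification, WAV I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import soundsight as ss
from soundsight.codec import column_slices, make_click


class TestEffectiveDuration:
    @pytest.mark.parametrize("base,ratio,expected", [
        (1.0, 0.5, 0.5),    # the short-soundscape group setting
        (1.0, 0.0, 1.0),    # default one frame per second
        (2.0, 0.25, 1.5),
    ])
    def test_values(self, base, ratio, expected):
        assert ss.effective_duration(base, ratio) == pytest.approx(expected)

    def test_full_compression_rejected(self):
        with pytest.raises(ValueError):
            ss.effective_duration(1.0, 1.0)

    @given(r1=st.integers(0, 98), r2=st.integers(0, 98))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_ratio(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = (r / 100 for r in sorted([r1, r2]))
        assert ss.effective_duration(1.0, hi) < ss.effective_duration(1.0, lo)


class TestRowFrequency:
    def test_scale_endpoints(self):
        assert ss.row_frequency(0, 64, 500, 5000) == pytest.approx(500.0)
        assert ss.row_frequency(63, 64, 500, 5000) == pytest.approx(5000.0)

    def test_log_linear_midpoint(self):
        # closed form: 500 * (5000/500)^(32/63)
        expected = 500.0 * 10.0 ** (32 / 63)
        assert ss.row_frequency(32, 64, 500, 5000) == pytest.approx(expected)

    def test_single_row_maps_to_f_min(self):
        assert ss.row_frequency(0, 1, 500, 5000) == 500.0

    @given(n=st.integers(2, 128), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_with_row(self, n, seed):
        rng = np.random.default_rng(seed)
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if i == j:
            return
        assert ss.row_frequency(i, n, 500, 5000) \
            < ss.row_frequency(j, n, 500, 5000)


class TestEncode:
    def test_black_image_is_silence(self):
        cfg = ss.CodecConfig()
        snd = ss.encode(np.zeros((28, 28)), cfg)
        assert len(snd.samples) == round(1.0 * cfg.sample_rate)
        assert np.all(snd.samples == 0.0)

    def test_top_row_pixel_dominates_at_f_max(self):
        """Single bright pixel in the top row, one column: FFT peak at
        f_max within one bin."""
        cfg = ss.CodecConfig()
        img = np.zeros((28, 1))
        img[0, 0] = 1.0
        snd = ss.encode(img, cfg)
        spec = np.abs(np.fft.rfft(snd.samples))
        freqs = np.fft.rfftfreq(len(snd.samples), 1 / cfg.sample_rate)
        df = freqs[1] - freqs[0]
        assert abs(freqs[spec.argmax()] - cfg.f_max) <= df

    def test_left_right_scan_orders_energy_in_time(self):
        cfg = ss.CodecConfig()
        left = np.zeros((16, 16))
        left[8, 0] = 1.0
        right = np.zeros((16, 16))
        right[8, 15] = 1.0
        for img, first_slice in ((left, 0), (right, 15)):
            snd = ss.encode(img, cfg)
            bounds = column_slices(len(snd.samples), 16)
            energies = np.array([
                np.sum(snd.samples[bounds[j]:bounds[j + 1]] ** 2)
                for j in range(16)])
            others = np.delete(energies, first_slice)
            assert energies[first_slice] > 10 * others.max()

    def test_linearity_before_normalization(self):
        """encode(a*I) equals a*encode(I) once peak normalization is
        factored out: the normalized waveforms coincide."""
        rng = np.random.default_rng(0)
        img = rng.uniform(0.2, 1.0, (12, 12))
        cfg = ss.CodecConfig()
        full = ss.encode(img, cfg)
        half = ss.encode(0.5 * img, cfg)
        np.testing.assert_allclose(half.samples, full.samples, atol=1e-12)

    def test_active_frequency_set_invariant_under_compression(self):
        """Compression changes slice durations, never the frequency code:
        the dominant spectral bins line up across ratios."""
        img = np.zeros((8, 4))
        img[2, :] = 1.0
        img[6, :] = 1.0
        peaks = []
        for r in (0.0, 0.5):
            cfg = ss.CodecConfig(compression_ratio=r)
            snd = ss.encode(img, cfg)
            spec = np.abs(np.fft.rfft(snd.samples))
            freqs = np.fft.rfftfreq(len(snd.samples), 1 / cfg.sample_rate)
            order = np.argsort(spec)[-2:]
            peaks.append(sorted(freqs[order]))
        np.testing.assert_allclose(peaks[0], peaks[1], rtol=5e-3)

    def test_click_prepended_and_excluded_from_scan(self):
        cfg = ss.CodecConfig(click_ms=50.0, compression_ratio=0.5)
        snd = ss.encode(np.ones((8, 8)) * 0.5, cfg)
        assert snd.click_samples == round(0.05 * cfg.sample_rate)
        assert snd.scan_duration == pytest.approx(0.5)
        assert np.max(np.abs(snd.samples)) <= cfg.peak_level + 1e-12

    def test_too_many_columns_rejected(self):
        cfg = ss.CodecConfig(base_duration=0.001)
        with pytest.raises(ValueError):
            ss.encode(np.ones((4, 64)), cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ss.CodecConfig(f_min=5000, f_max=500)
        with pytest.raises(ValueError):
            ss.CodecConfig(compression_ratio=1.0)
        with pytest.raises(ValueError):
            ss.CodecConfig(sample_rate=8000, f_max=5000)


class TestDecodePeaks:
    def test_one_pixel_round_trip(self):
        cfg = ss.CodecConfig()
        img = np.zeros((16, 16))
        img[3, 5] = 1.0
        rec = ss.decode_peaks(ss.encode(img, cfg), 16, 16)
        assert np.unravel_index(rec.argmax(), rec.shape) == (3, 5)

    def test_silence_decodes_to_zero(self):
        rec = ss.decode_peaks(ss.encode(np.zeros((8, 8)), ss.CodecConfig()),
                              8, 8)
        assert np.all(rec == 0.0)

    def test_sparse_round_trip_correlation(self):
        rng = np.random.default_rng(5)
        img = np.zeros((16, 16))
        idx = rng.choice(256, size=5, replace=False)
        img[np.unravel_index(idx, img.shape)] = 1.0
        rec = ss.decode_peaks(ss.encode(img, ss.CodecConfig()), 16, 16)
        corr = np.corrcoef(img.ravel(), rec.ravel())[0, 1]
        assert corr >= 0.8


class TestWavIO:
    def test_round_trip_within_quantization(self, tmp_path):
        cfg = ss.CodecConfig()
        snd = ss.encode(np.random.default_rng(1).uniform(0, 1, (8, 8)), cfg)
        path = tmp_path / "scape.wav"
        ss.write_wav(snd, path)
        back = ss.read_wav(path)
        assert back.sample_rate == cfg.sample_rate
        assert np.max(np.abs(back.samples - snd.samples)) <= 2.0 ** -15

    def test_header_frame_count(self, tmp_path):
        import wave
        snd = ss.encode(np.ones((4, 4)), ss.CodecConfig())
        path = tmp_path / "one_second.wav"
        ss.write_wav(snd, path)
        with wave.open(str(path)) as wf:
            assert wf.getnframes() == 22000
            assert wf.getframerate() == 22000
            assert wf.getnchannels() == 1
            assert wf.getsampwidth() == 2

    def test_clipped_input_rejected(self, tmp_path):
        bad = ss.Soundscape(samples=np.array([0.0, 1.5]), sample_rate=22000,
                            effective_duration=1.0)
        with pytest.raises(ValueError):
            ss.write_wav(bad, tmp_path / "x.wav")

    def test_empty_path_rejected(self):
        snd = ss.encode(np.ones((4, 4)), ss.CodecConfig())
        with pytest.raises(ValueError):
            ss.write_wav(snd, "")
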