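"""Gammatone front-end: ERB spacing, impulse response, framing, compression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maxcause import cochleagram as coch
from maxcause.synth import Waveform, synth_waveform


def erb_rate_oracle(f):
    """Independent Glasberg-Moore ERB-rate transform (Slaney's constants)."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=float))


def erb_rate_oracle_inv(e):
    return (10.0 ** (np.asarray(e) / 21.4) - 1.0) / 0.00437


class TestERBCenterFrequencies:
    def test_degenerate_single_channel(self):
        np.testing.assert_allclose(coch.erb_center_frequencies(1, 500.0, 500.0), [500.0])

    def test_paper_range_endpoints_and_count(self):
        cf = coch.erb_center_frequencies(32, 1000.0, 22050.0)
        assert len(cf) == 32
        assert cf[0] == 1000.0 and cf[-1] == 22050.0
        assert np.all(np.diff(cf) > 0)

    def test_matches_independent_erb_rate_closed_form(self):
        cf = coch.erb_center_frequencies(32, 1000.0, 22050.0)
        e = np.linspace(erb_rate_oracle(1000.0), erb_rate_oracle(22050.0), 32)
        np.testing.assert_allclose(cf, erb_rate_oracle_inv(e), atol=0.1)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            coch.erb_center_frequencies(8, 2000.0, 1000.0)


class TestGammatoneImpulseResponse:
    def test_zero_at_origin_for_order_four(self):
        cfg = coch.FilterbankConfig()
        assert coch.gammatone_impulse_response(0.0, cfg, 1000.0) == 0.0

    def test_matches_direct_formula_evaluation(self):
        # independent arithmetic oracle at t = 1 ms
        cfg = coch.FilterbankConfig(bw_factor=1.0, phase=0.0)
        t, fc = 1e-3, 1000.0
        b = 24.7 + fc / 9.26449
        expected = t**3 * np.exp(-2 * np.pi * b * t) * np.cos(2 * np.pi * fc * t)
        got = coch.gammatone_impulse_response(t, cfg, fc)
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        t=st.floats(min_value=0.0, max_value=0.05),
        fc=st.floats(min_value=200.0, max_value=20000.0),
    )
    def test_envelope_bound(self, t, fc):
        cfg = coch.FilterbankConfig()
        b = cfg.bw_factor * (24.7 + fc / 9.26449)
        g = coch.gammatone_impulse_response(t, cfg, fc)
        assert abs(g) <= t ** 3 * np.exp(-2 * np.pi * b * t) + 1e-300

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            coch.gammatone_impulse_response(-1e-3, coch.FilterbankConfig(), 1000.0)


class TestFilterbank:
    def test_zero_input_zero_output_and_linearity(self):
        cfg = coch.FilterbankConfig(n_channels=8)
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        zero = coch.apply_filterbank(np.zeros(2000), cfg, 44100.0)
        assert np.all(zero == 0)
        b1 = coch.apply_filterbank(x, cfg, 44100.0)
        b3 = coch.apply_filterbank(3.0 * x, cfg, 44100.0)
        np.testing.assert_allclose(b3, 3.0 * b1, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("impl", ["fir", "iir"])
    def test_tone_at_center_frequency_peaks_in_its_channel(self, impl):
        cfg = coch.FilterbankConfig(filter_impl=impl)
        cf = cfg.center_frequencies()
        k = 10
        w = synth_waveform([{"kind": "tone", "freq": float(cf[k])}], 0.1, 44100.0, seed=0)
        bands = coch.apply_filterbank(w.samples, cfg, w.rate)
        rms = np.sqrt(np.mean(bands[:, 2000:] ** 2, axis=1))  # skip onset transient
        assert int(np.argmax(rms)) == k

    def test_rate_below_2fmax_rejected(self):
        with pytest.raises(ValueError):
            coch.apply_filterbank(np.zeros(100), coch.FilterbankConfig(), 8000.0)


class TestFrameRMS:
    def test_constant_signal_rms_is_its_magnitude(self):
        cfg = coch.FrameConfig()
        x = np.full((3, 4410), -2.5)
        out = coch.frame_rms(x, cfg, 44100.0)
        np.testing.assert_allclose(out, 2.5, rtol=1e-12)

    def test_160ms_gives_15_frames(self):
        cfg = coch.FrameConfig(window=0.020, step=0.010)
        x = np.random.default_rng(0).normal(size=(2, 7056))
        assert coch.frame_rms(x, cfg, 44100.0).shape == (2, 15)

    def test_matches_brute_force_per_frame_oracle(self):
        cfg = coch.FrameConfig(window=0.020, step=0.010)
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        out = coch.frame_rms(x, cfg, 44100.0)
        w, h = 882, 441
        for t in range(out.shape[-1]):
            seg = x[t * h : t * h + w]
            assert out[t] == pytest.approx(np.sqrt(np.mean(seg**2)), rel=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            coch.frame_rms(np.zeros(100), coch.FrameConfig(), 44100.0)

    @settings(derandomize=True, max_examples=60)
    @given(n_extra=st.integers(min_value=0, max_value=5000))
    def test_frame_count_formula(self, n_extra):
        cfg = coch.FrameConfig(window=0.020, step=0.010)
        L = 882 + n_extra
        x = np.ones(L)
        out = coch.frame_rms(x, cfg, 44100.0)
        assert out.shape[-1] == (L - 882) // 441 + 1


class TestCompress:
    def test_closed_form_values_and_monotonicity(self):
        assert coch.compress(np.array(0.0)) == 0.0
        assert coch.compress(np.array(3.0)) == pytest.approx(10.0, rel=1e-12)
        x = np.linspace(0, 10, 100)
        assert np.all(np.diff(coch.compress(x)) > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            coch.compress(np.array([-0.1]))


class TestSnippets:
    def _wave(self, ms):
        n = int(round(ms / 1000 * 44100))
        return Waveform(np.arange(n, dtype=float), 44100.0)

    def test_exact_length_gives_one_snippet(self):
        out = coch.cut_snippets(self._wave(160), coch.FrameConfig())
        assert len(out) == 1

    def test_hop_is_length_minus_overlap(self):
        out = coch.cut_snippets(self._wave(288), coch.FrameConfig())
        assert len(out) == 2
        hop = int(round(0.128 * 44100))
        assert out[1].samples[0] == hop

    def test_trailing_remainder_dropped(self):
        assert len(coch.cut_snippets(self._wave(287), coch.FrameConfig())) == 1

    def test_too_short_waveform_yields_empty_list(self):
        assert coch.cut_snippets(self._wave(100), coch.FrameConfig()) == []


class TestBuildDataset:
    def test_rows_unit_norm_D480_and_silence_dropped(self):
        fb = coch.FilterbankConfig()
        fr = coch.FrameConfig()
        w1 = synth_waveform([{"kind": "tone", "freq": 2000.0}], 0.16, seed=0)
        w2 = synth_waveform([{"kind": "chirp", "f0": 1500.0, "f1": 6000.0}], 0.16, seed=1)
        silence = Waveform(np.zeros_like(w1.samples), w1.rate)
        Y, meta = coch.build_dataset([w1, w2, silence], fb, fr)
        assert Y.shape == (2, 480)
        np.testing.assert_allclose(np.linalg.norm(Y, axis=1), 1.0, atol=1e-12)
        assert meta["n_dropped"] == 1

    def test_front_end_deterministic(self):
        fb = coch.FilterbankConfig()
        fr = coch.FrameConfig()
        w = synth_waveform([{"kind": "tone", "freq": 2000.0}], 0.16, seed=0)
        c1 = coch.waveform_to_cochleagram(w, fb, fr)
        c2 = coch.waveform_to_cochleagram(w, fb, fr)
        np.testing.assert_array_equal(c1.values, c2.values)
        assert c1.values.min() >= 0


class TestFileIO:
    def test_wav_roundtrip_with_downmix_and_resample(self, tmp_path):
        from maxcause.synth import save_waveform_wav
        w = synth_waveform([{"kind": "tone", "freq": 2000.0}], 0.05, 44100.0, seed=0)
        p = tmp_path / "tone.wav"
        save_waveform_wav(w, p)
        back = coch.read_waveform(p)
        assert back.rate == 44100.0
        np.testing.assert_allclose(back.samples, w.samples, atol=1e-6)
        # stereo int16 at 22.05 kHz: downmixed, rescaled, resampled
        from scipy.io import wavfile
        stereo = (np.stack([w.samples[::2], w.samples[::2]], axis=1) * 32767).astype(np.int16)
        p2 = tmp_path / "stereo.wav"
        wavfile.write(p2, 22050, stereo)
        back2 = coch.read_waveform(p2)
        assert back2.rate == 44100.0
        assert abs(len(back2.samples) - len(w.samples)) <= 2

    def test_dataset_mat_csv_export(self, tmp_path):
        from scipy.io import loadmat
        fb, fr = coch.FilterbankConfig(), coch.FrameConfig()
        w = synth_waveform([{"kind": "tone", "freq": 2000.0}], 0.16, seed=0)
        Y, meta = coch.build_dataset([w], fb, fr)
        coch.save_dataset(Y, meta, tmp_path)
        mat = loadmat(tmp_path / "dataset.mat")
        np.testing.assert_allclose(mat["Y"], Y)
        assert (tmp_path / "dataset.csv").exists()
        assert (tmp_path / "center_freqs.csv").exists()

    def test_ground_truth_export_writes_manifest(self, tmp_path):
        from maxcause import synth as s
        gt = s.make_ground_truth_fields("bars", (4, 4), 6, seed=3)
        s.save_ground_truth(gt, tmp_path, layout="bars")
        text = (tmp_path / "manifest.txt").read_text()
        assert "layout: bars" in text and "H: 6" in text and "D: 16" in text
        assert (tmp_path / "ground_truth.mat").exists()
        assert (tmp_path / "ground_truth_fields.csv").exists()
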