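"""Segmentation chain: wavelet thresholding, Shannon envelope, UACF, cutting."""

import numpy as np
import pytest

from heartkit import RunConfig
from heartkit.errors import (
    ConstantEnvelope,
    DepthError,
    EmptyInput,
    NoPeriodicity,
)
from heartkit.pipeline import process_recording
from heartkit.segmentation import (
    EnvelopeSeries,
    WaveletConfig,
    adaptive_threshold,
    estimate_cycle_uacf,
    shannon_envelope,
    standardize_envelope,
    threshold_coeffs,
    wavelet_low_freq_extract,
)
from heartkit.signal_io import PCGRecording
from heartkit.synth import SynthConfig, synth_recording
from heartkit.wavelet import daubechies_filter, wavedec, waverec


def rec_of(x, rate=2000):
    return PCGRecording(id="t", samples=np.asarray(x, float), sample_rate=rate)


class TestAdaptiveThreshold:
    @pytest.mark.parametrize(
        "C,f,expected",
        [
            ([1, 1, 1, 1], 3.7, 1.0),  # zero variance
            ([0, 2], 1.0, 2.0),  # mean 1, population sigma 1
            ([3, -1, 2], 0.0, 2.0),  # f=0 reduces to mean(|C|)
        ],
    )
    def test_arithmetic(self, C, f, expected):
        assert adaptive_threshold(np.array(C, float), f) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInput):
            adaptive_threshold(np.array([]), 1.0)


class TestThresholdCoeffs:
    # keep_mode='below' mirrors the printed rule c~_i = c_i if |c_i| < thr
    def test_below_mode_keeps_small_magnitudes(self):
        cfg = WaveletConfig(keep_mode="below")
        out = threshold_coeffs(np.array([0.5, 3.0]), 1.0, cfg)
        assert np.allclose(out, [0.5, 0.0])

    def test_below_mode_magnitude_zeroes_large_negative(self):
        cfg = WaveletConfig(keep_mode="below")
        out = threshold_coeffs(np.array([-5.0, 0.1]), 1.0, cfg)
        assert np.allclose(out, [0.0, 0.1])

    def test_above_mode_is_hard_thresholding(self):
        out = threshold_coeffs(np.array([0.5, -3.0, 1.5]), 1.0)
        assert np.allclose(out, [0.0, -3.0, 1.5])

    @pytest.mark.parametrize("mode", ["below", "above"])
    def test_strict_inequality_at_boundary(self, mode):
        cfg = WaveletConfig(keep_mode=mode)
        out = threshold_coeffs(np.array([2.0, -2.0, 2.0]), 2.0, cfg)
        assert np.allclose(out, 0.0)


class TestWaveletTransform:
    def test_db2_matches_published_coefficients(self):
        expected = [0.4829629131, 0.8365163037, 0.2241438680, -0.1294095226]
        assert np.allclose(daubechies_filter(2), expected, atol=1e-9)

    @pytest.mark.parametrize("n", [4096, 4097, 10007])
    def test_perfect_reconstruction(self, rng, n):
        x = rng.standard_normal(n)
        assert np.sqrt(np.mean((waverec(wavedec(x)) - x) ** 2)) < 1e-8

    def test_too_short_for_depth(self):
        with pytest.raises(DepthError):
            wavedec(np.arange(16.0), order=6, levels=5)


class TestLowFreqExtract:
    def test_zero_in_zero_out(self):
        out = wavelet_low_freq_extract(rec_of(np.zeros(4000)))
        assert np.allclose(out.samples, 0.0)

    def test_lowers_spectral_centroid(self):
        rec, _ = synth_recording(SynthConfig(seed=3, snr_db=10.0), "normal")
        out = wavelet_low_freq_extract(rec)

        def centroid(x):
            spec = np.abs(np.fft.rfft(x))
            freqs = np.fft.rfftfreq(x.size, 1 / 2000)
            return np.sum(freqs * spec) / np.sum(spec)

        assert centroid(out.samples) < centroid(rec.samples)

    def test_untouched_reconstruction_is_identity(self):
        # thresholding disabled via keep-everything config (infinite threshold)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        dec = wavedec(x)
        assert np.sqrt(np.mean((waverec(dec) - x) ** 2)) < 1e-8


class TestShannonEnvelope:
    def test_zero_frame_gives_zero(self):
        env = shannon_envelope(rec_of(np.zeros(100)), frame_len=10, hop=5)
        assert np.allclose(env.values, 0.0)

    def test_unit_samples_give_zero(self):
        x = np.ones(100)
        x[::2] = -1.0
        env = shannon_envelope(rec_of(x), frame_len=10, hop=5)
        assert np.allclose(env.values, 0.0)  # e=1 -> log e = 0

    def test_matches_bruteforce_summation(self, rng):
        x = rng.uniform(-1, 1, 500)
        frame_len, hop = 40, 20
        env = shannon_envelope(rec_of(x), frame_len, hop)
        n_frames = (x.size - frame_len) // hop + 1
        assert env.values.size == n_frames
        for k in range(n_frames):
            total = 0.0
            for j in range(frame_len):
                e = x[k * hop + j] ** 2
                if e > 0:
                    total += e * np.log(e)
            assert env.values[k] == pytest.approx(-total / frame_len, abs=1e-12)


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        env = shannon_envelope(rec_of(rng.standard_normal(2000)), 40, 20)
        out = standardize_envelope(env)
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std() - 1.0) < 1e-9

    def test_affine_invariance(self, rng):
        base = rng.uniform(0, 1, 50)
        e1 = EnvelopeSeries(values=base.copy(), frame_len=40, hop=20, sample_rate=2000)
        e2 = EnvelopeSeries(values=3.5 * base + 2.0, frame_len=40, hop=20, sample_rate=2000)
        assert np.allclose(
            standardize_envelope(e1).values, standardize_envelope(e2).values, atol=1e-9
        )

    def test_constant_envelope_rejected(self):
        env = EnvelopeSeries(values=np.full(10, 3.0), frame_len=40, hop=20, sample_rate=2000)
        with pytest.raises(ConstantEnvelope):
            standardize_envelope(env)


class TestUACF:
    def test_impulse_train_period_recovered(self):
        # 1 s period at 2 kHz, envelope hop 1 -> lag 2000 +- 1
        x = np.zeros(8000)
        x[::2000] = 1.0
        env = EnvelopeSeries(values=x, frame_len=2, hop=1, sample_rate=2000)
        est = estimate_cycle_uacf(env)
        assert abs(est.period_samples - 2000) <= 1

    def test_synthetic_75_bpm(self):
        rec, _ = synth_recording(SynthConfig(bpm=75.0, seed=5), "normal")
        env = standardize_envelope(
            shannon_envelope(wavelet_low_freq_extract(rec), 40, 20)
        )
        est = estimate_cycle_uacf(env)
        assert est.period_seconds == pytest.approx(0.8, rel=0.05)
        assert 0.0 <= est.confidence <= 1.0

    def test_constant_envelope_has_no_period(self):
        env = EnvelopeSeries(values=np.zeros(8000), frame_len=2, hop=1, sample_rate=2000)
        with pytest.raises(NoPeriodicity):
            estimate_cycle_uacf(env)


class TestSegmentRecording:
    def test_eight_beats_recovered_with_s1_aligned_starts(self, run_cfg):
        # 8 cycles at the default 75 bpm; starts must hit generator S1 onsets
        rec, gt = synth_recording(SynthConfig(duration=6.3, seed=2), "normal")
        assert gt.n_beats == 8
        segs, _ = process_recording(rec, run_cfg)
        assert len(segs) == 8
        gts = np.array(gt.s1_times)
        for s in segs:
            err = np.min(np.abs(gts - s.start / 2000.0))
            assert err <= 0.025, f"onset off by {err * 1e3:.1f} ms"

    def test_segments_disjoint_ordered_in_bounds(self, run_cfg, clean_recording):
        rec, _ = clean_recording
        segs, _ = process_recording(rec, run_cfg)
        assert len(segs) > 0
        prev_end = 0
        for s in segs:
            assert 0 <= s.start < s.end <= rec.samples.size
            assert s.start >= prev_end
            prev_end = s.end

    def test_too_short_recording_yields_empty(self, run_cfg):
        rec, _ = synth_recording(SynthConfig(duration=8.0, seed=2), "normal")
        short = PCGRecording(id="s", samples=rec.samples[:900], sample_rate=2000)
        from heartkit.segmentation import CycleEstimate, segment_recording

        env = standardize_envelope(shannon_envelope(short, 40, 20))
        cyc = CycleEstimate(period_samples=1600, period_seconds=0.8, confidence=0.9)
        with pytest.warns(UserWarning):
            segs = segment_recording(short, env, cyc)
        assert segs == []
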