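"""Mel scale, filter bank geometry, and the MFCC chain."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import weevilsense as ws
from weevilsense.mfcc import frame_count

from conftest import UNIT_SR, sine_segment


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert ws.hz_to_mel(0.0) == 0.0

    def test_reference_point_700hz(self):
        assert ws.hz_to_mel(700.0) == pytest.approx(2595.0 * np.log10(2.0), abs=1e-9)

    @pytest.mark.parametrize("f", [100.0, 1000.0, 8000.0])
    def test_round_trip(self, f):
        assert ws.mel_to_hz(ws.hz_to_mel(f)) == pytest.approx(f, abs=1e-9)

    def test_strictly_increasing(self):
        f = np.linspace(0, 8000, 200)
        assert np.all(np.diff(ws.hz_to_mel(f)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ws.hz_to_mel(-1.0)


@pytest.fixture(scope="module")
def bank():
    cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
    return ws.build_filterbank(cfg, UNIT_SR)


class TestFilterBank:

    def test_centers_uniform_on_mel_scale(self, bank):
        mel_centers = ws.hz_to_mel(bank.center_frequencies_hz)
        spacing = np.diff(mel_centers)
        assert np.allclose(spacing, spacing[0], atol=1e-9)

    def test_center_bin_holds_filter_maximum(self, bank):
        for row in bank.weights:
            assert row[row.argmax()] == row.max() > 0

    def test_alternate_filters_have_disjoint_support(self, bank):
        for k in range(len(bank.weights) - 2):
            assert not np.any((bank.weights[k] > 0) & (bank.weights[k + 2] > 0))

    def test_weights_nonnegative_and_triangular(self, bank):
        assert np.all(bank.weights >= 0)
        for row in bank.weights:
            support = np.flatnonzero(row > 0)
            peak = row.argmax()
            assert np.all(np.diff(row[support[0] : peak + 1]) >= -1e-12)
            assert np.all(np.diff(row[peak : support[-1] + 1]) <= 1e-12)

    def test_too_dense_bank_rejected(self):
        cfg = ws.MfccConfig(frame_length=64, hop=32, n_fft=64, n_mel_filters=40,
                            n_coefficients=13)
        with pytest.raises(ValueError):
            ws.build_filterbank(cfg, UNIT_SR)


class TestMfcc:
    def test_frame_count_formula(self):
        cfg = ws.MfccConfig(frame_length=1102, hop=441)
        assert frame_count(44100, cfg) == (44100 - 1102) // 441 + 1 == 98

    def test_all_zero_segment_constant_coefficients(self):
        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        seg = ws.AudioSegment(samples=np.zeros(int(UNIT_SR)), sample_rate=UNIT_SR)
        matrix = ws.mfcc(seg, cfg)
        assert np.allclose(matrix.coefficients, matrix.coefficients[0])

    def test_tone_at_filter_center_dominates_bank(self):
        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        bank = ws.build_filterbank(cfg, UNIT_SR)
        center = float(bank.center_frequencies_hz[12])
        log_e = ws.mel_spectrogram(sine_segment(center), cfg, bank=bank)
        assert np.argmax(log_e.mean(axis=0)) == 12

    def test_shorter_than_frame_rejected(self):
        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        seg = ws.AudioSegment(samples=np.zeros(10), sample_rate=UNIT_SR)
        with pytest.raises(ValueError):
            ws.mfcc(seg, cfg)

    def test_polarity_invariance(self):
        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(UNIT_SR))
        pos = ws.mfcc(ws.AudioSegment(samples=x, sample_rate=UNIT_SR), cfg)
        neg = ws.mfcc(ws.AudioSegment(samples=-x, sample_rate=UNIT_SR), cfg)
        np.testing.assert_allclose(pos.coefficients, neg.coefficients, atol=1e-9)

    def test_c0_monotone_in_gain(self):
        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(UNIT_SR))
        c0 = [
            ws.mfcc(ws.AudioSegment(samples=g * x, sample_rate=UNIT_SR), cfg)
            .coefficients[:, 0]
            .mean()
            for g in (0.1, 1.0, 10.0)
        ]
        assert c0[0] < c0[1] < c0[2]

    def test_dct_of_mel_spectrogram_reproduces_mfcc(self):
        from scipy.fft import dct

        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        seg = sine_segment(1234.0)
        log_e = ws.mel_spectrogram(seg, cfg)
        manual = dct(log_e, type=2, norm="ortho", axis=1)[:, : cfg.n_coefficients]
        np.testing.assert_allclose(ws.mfcc(seg, cfg).coefficients, manual, atol=1e-12)

    def test_dct_orthonormal_round_trip(self):
        from scipy.fft import dct, idct

        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        log_e = ws.mel_spectrogram(sine_segment(2500.0), cfg)
        recovered = idct(dct(log_e, type=2, norm="ortho", axis=1), type=2, norm="ortho", axis=1)
        np.testing.assert_allclose(recovered, log_e, atol=1e-9)

    def test_adult_band_segment_peaks_in_4_to_5_khz(self, small_audio_scene):
        cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
        bank = ws.build_filterbank(cfg, UNIT_SR)
        seg = next(
            s for s in small_audio_scene.segments if s.label == ws.Activity.ADULT_WALKING
        )
        log_e = ws.mel_spectrogram(seg, cfg, bank=bank)
        peak_center = bank.center_frequencies_hz[np.argmax(log_e.mean(axis=0))]
        assert 4000.0 <= peak_center <= 5000.0


def _naive_mfcc(x, sr, cfg):
    """Straight-line loop-based MFCC, written independently of the package."""
    n_fft = cfg.resolved_n_fft()
    n = cfg.frame_length
    window = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(n) / n)  # periodic Hamming
    mel_lo, mel_hi = 0.0, 2595.0 * np.log10(1.0 + (sr / 2.0) / 700.0)
    points = [
        700.0 * (10.0 ** ((mel_lo + i * (mel_hi - mel_lo) / (cfg.n_mel_filters + 1)) / 2595.0) - 1.0)
        for i in range(cfg.n_mel_filters + 2)
    ]
    bin_f = [b * sr / n_fft for b in range(n_fft // 2 + 1)]
    out = []
    start = 0
    while start + n <= len(x):
        frame = x[start : start + n] * window
        spec = np.abs(np.fft.rfft(frame, n_fft)) ** 2
        coeffs = []
        energies = []
        for m in range(cfg.n_mel_filters):
            lo, ce, hi = points[m], points[m + 1], points[m + 2]
            e = 0.0
            for b, f in enumerate(bin_f):
                if lo < f < ce:
                    e += spec[b] * (f - lo) / (ce - lo)
                elif ce <= f < hi:
                    e += spec[b] * (hi - f) / (hi - ce)
            energies.append(np.log(max(e, cfg.log_floor)))
        m_count = cfg.n_mel_filters
        for k in range(cfg.n_coefficients):
            scale = np.sqrt(1.0 / m_count) if k == 0 else np.sqrt(2.0 / m_count)
            coeffs.append(
                scale
                * sum(
                    energies[j] * np.cos(np.pi * k * (2 * j + 1) / (2 * m_count))
                    for j in range(m_count)
                )
            )
        out.append(coeffs)
        start += cfg.hop
    return np.array(out)


def test_agreement_with_independent_mfcc_reference(small_audio_scene):
    """Coefficient trajectories rank-correlate > 0.99 with a naive oracle."""
    cfg = ws.MfccConfig(frame_length=400, hop=160)  # 25/10 ms at 16 kHz
    rng = np.random.default_rng(9)
    picks = rng.permutation(len(small_audio_scene.segments))[:10]
    for i in picks:
        seg = small_audio_scene.segments[i]
        short = ws.AudioSegment(samples=seg.samples[:3200], sample_rate=seg.sample_rate)
        ours = ws.mfcc(short, cfg).coefficients
        ref = _naive_mfcc(short.samples, short.sample_rate, cfg)
        assert ours.shape == ref.shape
        for k in range(cfg.n_coefficients):
            rho = spearmanr(ours[:, k], ref[:, k]).statistic
            assert rho > 0.99
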