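"""Mel-frequency cepstral coefficient front-end, built from first principles.

The chain is the textbook one: slice the segment into short overlapping
frames, window each frame, take the magnitude (power) spectrum, pool it
through a bank of triangular filters spaced uniformly on the Mel scale,
log-compress, and decorrelate with an orthonormal DCT-II. The Mel scale
is the standard ``2595 * log10(1 + f / 700)`` mapping. Per-segment
classifier features are the mean and standard deviation of each
coefficient across frames.

Defaults: 25 ms frames, 10 ms hop, Hamming window, FFT size the next
power of two, 26 filters, 13 coefficients, power spectrum into the bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import dct
from scipy.signal.windows import get_window

from .audio_dsp import AudioSegment


def hz_to_mel(f):
    """Map frequency in Hz to Mel; strictly increasing, 0 maps to 0."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    """Inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("Mel value must be non-negative")
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


@dataclass(frozen=True)
class MfccConfig:
    """Framing, window, filter-bank and DCT parameters.

    Lengths are in samples; use :meth:`for_sample_rate` to derive them
    from durations. ``f_max=None`` means the Nyquist frequency.
    """

    frame_length: int = 1103
    hop: int = 441
    window: str = "hamming"
    n_fft: int | None = None
    n_mel_filters: int = 26
    n_coefficients: int = 13
    f_min: float = 0.0
    f_max: float | None = None
    log_floor: float = 1e-10
    use_power: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.n_coefficients <= self.n_mel_filters:
            raise ValueError("need 0 < n_coefficients <= n_mel_filters")
        if not 0 < self.hop <= self.frame_length:
            raise ValueError("need 0 < hop <= frame_length")
        if self.n_fft is not None and self.n_fft < self.frame_length:
            raise ValueError("n_fft must be >= frame_length")
        if self.window not in ("hamming", "hann", "rect"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    @classmethod
    def for_sample_rate(
        cls, sample_rate: float, frame_s: float = 0.025, hop_s: float = 0.010, **kwargs
    ) -> "MfccConfig":
        return cls(
            frame_length=int(round(frame_s * sample_rate)),
            hop=int(round(hop_s * sample_rate)),
            **kwargs,
        )

    def resolved_n_fft(self) -> int:
        if self.n_fft is not None:
            return self.n_fft
        return 1 << (self.frame_length - 1).bit_length()

    def resolved_f_max(self, sample_rate: float) -> float:
        f_max = sample_rate / 2.0 if self.f_max is None else self.f_max
        if not self.f_min < f_max <= sample_rate / 2.0:
            raise ValueError("need f_min < f_max <= Nyquist")
        return f_max


@dataclass(frozen=True)
class MelFilterBank:
    """Triangular filters as a (n_filters, n_fft//2 + 1) weight matrix."""

    weights: np.ndarray
    center_frequencies_hz: np.ndarray
    edge_frequencies_hz: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class MfccMatrix:
    """Per-frame coefficients (frames x n_coefficients) with frame times."""

    coefficients: np.ndarray
    frame_times: np.ndarray


def frame_count(n_samples: int, cfg: MfccConfig) -> int:
    if n_samples < cfg.frame_length:
        return 0
    return (n_samples - cfg.frame_length) // cfg.hop + 1


def build_filterbank(cfg: MfccConfig, sample_rate: float) -> MelFilterBank:
    """Triangular filters with edges/centers uniform on the Mel scale.

    ``n_mel_filters + 2`` points are placed uniformly in Mel between
    ``f_min`` and ``f_max``; filter k rises from point k to k+1 and
    falls to k+2, evaluated at the FFT bin frequencies.
    """
    f_max = cfg.resolved_f_max(sample_rate)
    n_fft = cfg.resolved_n_fft()
    mel_points = np.linspace(hz_to_mel(cfg.f_min), hz_to_mel(f_max), cfg.n_mel_filters + 2)
    hz_points = mel_to_hz(mel_points)
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft

    weights = np.zeros((cfg.n_mel_filters, len(bin_freqs)))
    for k in range(cfg.n_mel_filters):
        lo, center, hi = hz_points[k], hz_points[k + 1], hz_points[k + 2]
        rising = (bin_freqs - lo) / (center - lo)
        falling = (hi - bin_freqs) / (hi - center)
        weights[k] = np.clip(np.minimum(rising, falling), 0.0, None)

    if np.any(weights.sum(axis=1) == 0):
        raise ValueError(
            "filter bank too dense for the FFT resolution: some filters cover no bin"
        )
    center_bins = weights.argmax(axis=1)
    if len(np.unique(center_bins)) != cfg.n_mel_filters:
        raise ValueError("filter bank too dense for the FFT resolution: duplicate centers")
    return MelFilterBank(
        weights=weights,
        center_frequencies_hz=hz_points[1:-1],
        edge_frequencies_hz=hz_points,
    )


def _frames(seg: AudioSegment, cfg: MfccConfig) -> np.ndarray:
    n = frame_count(len(seg.samples), cfg)
    if n == 0:
        raise ValueError("segment is shorter than one analysis frame")
    idx = np.arange(cfg.frame_length)[None, :] + cfg.hop * np.arange(n)[:, None]
    return seg.samples[idx]


def _window(cfg: MfccConfig) -> np.ndarray:
    if cfg.window == "rect":
        return np.ones(cfg.frame_length)
    # periodic windows, the spectral-analysis convention
    return get_window(cfg.window, cfg.frame_length, fftbins=True)


def mel_spectrogram(
    seg: AudioSegment, cfg: MfccConfig, bank: MelFilterBank | None = None
) -> np.ndarray:
    """Log Mel filter-bank energies, shape (frames, n_mel_filters)."""
    if bank is None:
        bank = build_filterbank(cfg, seg.sample_rate)
    frames = _frames(seg, cfg) * _window(cfg)
    spec = np.abs(np.fft.rfft(frames, n=cfg.resolved_n_fft(), axis=1))
    if cfg.use_power:
        spec = spec**2
    energies = spec @ bank.weights.T
    return np.log(np.maximum(energies, cfg.log_floor))


def mfcc(seg: AudioSegment, cfg: MfccConfig, bank: MelFilterBank | None = None) -> MfccMatrix:
    """MFCCs per frame: DCT-II (orthonormal) of the log filter-bank energies."""
    log_energies = mel_spectrogram(seg, cfg, bank=bank)
    coeffs = dct(log_energies, type=2, norm="ortho", axis=1)[:, : cfg.n_coefficients]
    n = coeffs.shape[0]
    times = seg.offset + (cfg.hop * np.arange(n) + cfg.frame_length / 2.0) / seg.sample_rate
    return MfccMatrix(coefficients=coeffs, frame_times=times)


def aggregate_features(matrix: MfccMatrix) -> np.ndarray:
    """Per-segment feature vector: mean then std of each coefficient."""
    c = matrix.coefficients
    return np.concatenate([c.mean(axis=0), c.std(axis=0)])


def save_mel_spectrogram_png(
    seg: AudioSegment, cfg: MfccConfig, path: str | Path, title: str = "Mel spectrogram"
) -> None:
    """Render the log Mel spectrogram to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bank = build_filterbank(cfg, seg.sample_rate)
    log_energies = mel_spectrogram(seg, cfg, bank=bank)
    fig, ax = plt.subplots(figsize=(8, 4))
    extent = (
        float(seg.offset),
        float(seg.offset + len(seg.samples) / seg.sample_rate),
        float(bank.center_frequencies_hz[0]),
        float(bank.center_frequencies_hz[-1]),
    )
    ax.imshow(log_energies.T, origin="lower", aspect="auto", extent=extent, cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Mel filter center (Hz)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
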