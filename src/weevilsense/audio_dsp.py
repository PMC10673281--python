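"""Waveform ingestion, segmentation, normalization, spectra and signal statistics.

Recordings are handled as mono float waveforms normalized to full scale
[-1, 1]. Long recordings are cut into fixed-length non-overlapping
segments (5 s by default, matching the acquisition protocol), each
segment is RMS-normalized so sensors of different sensitivity are
comparable, and per-segment statistics (dynamic range, crest factor,
autocorrelation time) and one-sided magnitude spectra are computed.
``dominant_band`` reduces a spectrum to the activity band holding the
most power, which doubles as a transparent baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .bands import Activity, BandScheme, DEFAULT_BANDS

_INT16_FULL_SCALE = 32768.0


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal with its sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class AudioSegment(Waveform):
    """A fixed-duration slice of a recording.

    ``offset`` is the slice's start time within the source recording;
    ``label`` is the behavioural class when known.
    """

    offset: float = 0.0
    label: Activity | None = None


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on bins from 0 to Nyquist."""

    frequencies: np.ndarray
    magnitude: np.ndarray
    n_samples: int

    def total_power(self) -> float:
        """Spectral power matching time-domain energy (Parseval).

        One-sided bins other than DC (and Nyquist for even lengths)
        carry both halves of the two-sided spectrum.
        """
        weights = np.full(len(self.magnitude), 2.0)
        weights[0] = 1.0
        if self.n_samples % 2 == 0:
            weights[-1] = 1.0
        return float(np.sum(weights * self.magnitude**2) / self.n_samples)

    def band_power(self, low: float, high: float) -> float:
        """Power integrated over bins with low <= f <= high."""
        sel = (self.frequencies >= low) & (self.frequencies <= high)
        weights = np.full(len(self.magnitude), 2.0)
        weights[0] = 1.0
        if self.n_samples % 2 == 0:
            weights[-1] = 1.0
        return float(np.sum((weights * self.magnitude**2)[sel]) / self.n_samples)


@dataclass(frozen=True)
class SignalStats:
    """Per-segment statistics in the sensor-comparison report layout."""

    minimum: float
    maximum: float
    mean: float
    dynamic_range_db: float
    crest_factor_db: float
    autocorrelation_time_s: float


@dataclass(frozen=True)
class BandPowerReport:
    """Dominant activity band plus the full power split."""

    band: Activity
    fractions: dict
    out_of_band_fraction: float


def read_wav(path: str | Path) -> Waveform:
    """Read a 16-bit PCM mono WAV as a full-scale-normalized waveform."""
    sample_rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data / _INT16_FULL_SCALE
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(samples=samples, sample_rate=float(sample_rate))


def write_wav(path: str | Path, waveform: Waveform) -> None:
    """Write a waveform as 16-bit PCM mono; samples are clipped to [-1, 1]."""
    clipped = np.clip(waveform.samples, -1.0, 1.0)
    pcm = np.round(clipped * (_INT16_FULL_SCALE - 1)).astype(np.int16)
    wavfile.write(path, int(waveform.sample_rate), pcm)


def segment(waveform: Waveform, seg_len: float) -> list[AudioSegment]:
    """Cut into consecutive non-overlapping segments of ``seg_len`` seconds.

    A trailing remainder shorter than ``seg_len`` is dropped; a waveform
    shorter than one segment yields an empty list.
    """
    if seg_len <= 0:
        raise ValueError("seg_len must be positive")
    n_per = int(round(seg_len * waveform.sample_rate))
    n_segments = len(waveform.samples) // n_per
    return [
        AudioSegment(
            samples=waveform.samples[i * n_per : (i + 1) * n_per],
            sample_rate=waveform.sample_rate,
            offset=i * n_per / waveform.sample_rate,
        )
        for i in range(n_segments)
    ]


def rms_normalize(seg: AudioSegment) -> AudioSegment:
    """Scale so the segment's RMS is exactly 1; shape is preserved."""
    rms = float(np.sqrt(np.mean(seg.samples**2)))
    if rms == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero segment")
    return replace(seg, samples=seg.samples / rms)


def spectrum(seg: AudioSegment) -> Spectrum:
    """One-sided magnitude spectrum of the raw (unwindowed) segment."""
    if len(seg.samples) == 0:
        raise ValueError("cannot compute the spectrum of an empty segment")
    mag = np.abs(np.fft.rfft(seg.samples))
    freqs = np.fft.rfftfreq(len(seg.samples), d=1.0 / seg.sample_rate)
    return Spectrum(frequencies=freqs, magnitude=mag, n_samples=len(seg.samples))


def signal_stats(seg: AudioSegment) -> SignalStats:
    """Min/max/mean plus dynamic range, crest factor and autocorrelation time.

    Crest factor is 20*log10(peak/RMS). Dynamic range is the dB ratio of
    the largest to the smallest nonzero absolute amplitude after 16-bit
    quantization, i.e. what the recording chain can actually resolve.
    Autocorrelation time is the smallest positive lag at which the
    normalized autocorrelation magnitude first falls below 0.1.
    """
    x = seg.samples
    if len(x) == 0 or not np.any(x):
        raise ValueError("signal statistics are undefined for an empty/all-zero segment")
    peak = float(np.max(np.abs(x)))
    rms = float(np.sqrt(np.mean(x**2)))
    quantized = np.round(x * (_INT16_FULL_SCALE - 1))
    nonzero = np.abs(quantized[quantized != 0])
    dynamic_range = 20.0 * np.log10(nonzero.max() / nonzero.min()) if len(nonzero) else 0.0
    return SignalStats(
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        mean=float(np.mean(x)),
        dynamic_range_db=float(dynamic_range),
        crest_factor_db=20.0 * float(np.log10(peak / rms)),
        autocorrelation_time_s=_autocorrelation_time(x, seg.sample_rate),
    )


def _autocorrelation_time(x: np.ndarray, sample_rate: float) -> float:
    n = len(x)
    # biased autocorrelation via FFT, normalized to r[0] = 1
    n_fft = 1 << (2 * n - 1).bit_length()
    spec = np.fft.rfft(x, n_fft)
    acf = np.fft.irfft(spec * np.conj(spec), n_fft)[:n]
    acf /= acf[0]
    below = np.flatnonzero(np.abs(acf[1:]) < 0.1)
    if len(below) == 0:
        return n / sample_rate
    return float(below[0] + 1) / sample_rate


def band_power_report(seg: AudioSegment, bands: BandScheme = DEFAULT_BANDS) -> BandPowerReport:
    """Integrate spectral power per activity band.

    Returns the band with the largest integrated power, the per-band
    power fractions, and the fraction of power outside every band.
    """
    bands.validate_for_sample_rate(seg.sample_rate)
    spec = spectrum(seg)
    total = spec.total_power()
    if total == 0.0:
        raise ValueError("band powers are undefined for an all-zero segment")
    fractions = {
        activity: spec.band_power(low, high) / total for activity, (low, high) in bands.items()
    }
    dominant = max(fractions, key=lambda a: (fractions[a], a.value))
    return BandPowerReport(
        band=dominant,
        fractions=fractions,
        out_of_band_fraction=max(0.0, 1.0 - sum(fractions.values())),
    )


def dominant_band(seg: AudioSegment, bands: BandScheme = DEFAULT_BANDS) -> Activity:
    """The activity band containing the largest integrated spectral power."""
    return band_power_report(seg, bands).band
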