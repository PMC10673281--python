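"""Synthetic acoustic scenes and scripted two-weevil video with ground truth.

Audio
-----
Each non-resting segment is a Poisson-timed train of short (5-20 ms)
white-noise bursts band-passed into the activity's frequency band
(mating 800-950 Hz, pupal movement 1-4 kHz, adult walking 4-5 kHz) with
an order-4 zero-phase Butterworth filter, normalized to unit RMS, plus
white Gaussian noise scaled to the scenario's SNR. Resting segments are
unit-RMS white noise only — resting *is* the background-noise class, so
its level does not depend on the SNR setting. The burst model emulates
the impulsive character of insect sounds; only the band placement is a
measured property.

Video
-----
Two dark elliptical weevils on a light background, with an optional
static darker "mango" region, act out a scripted chase → overlap
(mating) → separation sequence. During the overlap phase the two
ellipses merge into a single connected component, which is exactly the
cue the video segmentation pipeline keys on. Ground-truth mating
intervals come straight from the script.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .audio_dsp import AudioSegment, Waveform, write_wav
from .bands import Activity, BandScheme, BAND_ACTIVITIES, DEFAULT_BANDS

LABEL_CSV_FIELDS = ("segment_index", "start_s", "end_s", "label")


@dataclass(frozen=True)
class AudioScenario:
    """Parameters of a synthetic acoustic scene.

    snr_db is 10*log10(signal power / noise power) over the whole
    segment; ``inf`` disables noise on the band-signal classes.
    """

    sample_rate: float = 44100.0
    segment_length: float = 5.0
    segments_per_class: int = 20
    snr_db: float = 30.0
    burst_rate: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.segments_per_class <= 0:
            raise ValueError("segments_per_class must be positive")
        if self.burst_rate <= 0:
            raise ValueError("burst_rate must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Known truth for a generated scene."""

    audio_labels: list | None = None
    video_events: list | None = None


@dataclass
class AudioScene:
    """Generated labeled segments plus the concatenated recording."""

    segments: list
    scenario: AudioScenario
    ground_truth: GroundTruth

    @property
    def waveform(self) -> Waveform:
        samples = np.concatenate([s.samples for s in self.segments])
        return Waveform(samples=samples, sample_rate=self.scenario.sample_rate)

    def label_rows(self) -> list[dict]:
        rows = []
        for i, seg in enumerate(self.segments):
            rows.append(
                {
                    "segment_index": i,
                    "start_s": seg.offset,
                    "end_s": seg.offset + seg.duration,
                    "label": seg.label.value,
                }
            )
        return rows

    def write(self, out_dir: str | Path, master_gain: float = 0.05) -> dict:
        """Write ``scene.wav`` (16-bit PCM) and ``labels.csv``; return paths.

        ``master_gain`` scales the unit-RMS segments so burst peaks stay
        well inside full scale.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wav_path = out_dir / "scene.wav"
        csv_path = out_dir / "labels.csv"
        wave = self.waveform
        write_wav(wav_path, Waveform(wave.samples * master_gain, wave.sample_rate))
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=LABEL_CSV_FIELDS)
            writer.writeheader()
            writer.writerows(self.label_rows())
        return {"wav": wav_path, "labels": csv_path}


def _burst_train(rng: np.random.Generator, n: int, sample_rate: float, rate: float) -> np.ndarray:
    """Poisson-timed Hann-enveloped white-noise bursts of 5-20 ms."""
    x = np.zeros(n)
    t = rng.exponential(1.0 / rate)
    while t < n / sample_rate:
        length = int(rng.uniform(0.005, 0.020) * sample_rate)
        start = int(t * sample_rate)
        burst = rng.standard_normal(min(length, n - start))
        x[start : start + len(burst)] += burst * np.hanning(len(burst))
        t += rng.exponential(1.0 / rate)
    if not np.any(x):  # a pathologically empty draw: place one central burst
        length = int(0.02 * sample_rate)
        start = (n - length) // 2
        x[start : start + length] = rng.standard_normal(length) * np.hanning(length)
    return x


def generate_audio(scenario: AudioScenario, bands: BandScheme = DEFAULT_BANDS) -> AudioScene:
    """Generate ``segments_per_class`` labeled segments for each activity.

    Segment order is a seeded shuffle so classes interleave as they
    would in a real recording; offsets index into the concatenated
    waveform. Deterministic under ``scenario.seed``.
    """
    bands.validate_for_sample_rate(scenario.sample_rate)
    rng = np.random.default_rng(scenario.seed)
    sr = scenario.sample_rate
    n = int(round(scenario.segment_length * sr))

    labels = [
        activity
        for activity in (*BAND_ACTIVITIES, Activity.RESTING)
        for _ in range(scenario.segments_per_class)
    ]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    sos = {
        activity: sps.butter(4, bands[activity], btype="bandpass", fs=sr, output="sos")
        for activity in BAND_ACTIVITIES
    }
    noise_scale = 0.0 if np.isinf(scenario.snr_db) else 10.0 ** (-scenario.snr_db / 20.0)

    segments = []
    for i, activity in enumerate(labels):
        if activity is Activity.RESTING:
            x = rng.standard_normal(n)
        else:
            burst = _burst_train(rng, n, sr, scenario.burst_rate)
            x = sps.sosfiltfilt(sos[activity], burst)
            x = x / np.sqrt(np.mean(x**2))
            if noise_scale > 0.0:
                x = x + noise_scale * rng.standard_normal(n)
        x = x / np.sqrt(np.mean(x**2))
        segments.append(
            AudioSegment(samples=x, sample_rate=sr, offset=i * scenario.segment_length,
                         label=activity)
        )
    return AudioScene(
        segments=segments,
        scenario=scenario,
        ground_truth=GroundTruth(audio_labels=[s.label for s in segments]),
    )


# ---------------------------------------------------------------------------
# video


@dataclass(frozen=True)
class ScriptPhase:
    """One behavioural phase spanning frames [start_frame, end_frame]."""

    phase: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.phase not in ("chase", "overlap", "separate"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.end_frame < self.start_frame:
            raise ValueError("phase must span at least one frame")


@dataclass(frozen=True)
class VideoScenario:
    """Frame geometry, timing, blob shape and the behavioural script."""

    frame_size: tuple = (240, 320)
    fps: float = 10.0
    script: tuple = (
        ScriptPhase("chase", 0, 49),
        ScriptPhase("overlap", 50, 219),
        ScriptPhase("separate", 220, 269),
    )
    blob_axes: tuple = (7.0, 12.0)
    background_intensity: int = 220
    blob_intensity: int = 40
    mango_intensity: int = 90
    include_mango: bool = True
    jitter_px: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        expected = self.script[0].start_frame
        for phase in self.script:
            if phase.start_frame != expected:
                raise ValueError("script phases must be contiguous, ordered, non-overlapping")
            expected = phase.end_frame + 1
        if self.script[0].start_frame != 0:
            raise ValueError("script must start at frame 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.script[-1].end_frame + 1

    @property
    def blob_area(self) -> float:
        """Expected single-weevil pixel area (ellipse area)."""
        return float(np.pi * self.blob_axes[0] * self.blob_axes[1])


def make_mating_script(
    fps: float = 10.0,
    chase_s: float = 5.0,
    mating_duration_s: float | None = None,
    separate_s: float = 5.0,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Build a chase → overlap → separate script.

    When ``mating_duration_s`` is None, the duration is drawn uniformly
    from 15-20 s: the 15-20 minute natural mating bout compressed to a
    desk-scale clip.
    """
    if mating_duration_s is None:
        if rng is None:
            rng = np.random.default_rng()
        mating_duration_s = float(rng.uniform(15.0, 20.0))
    n_chase = int(round(chase_s * fps))
    n_overlap = int(round(mating_duration_s * fps))
    n_sep = int(round(separate_s * fps))
    return (
        ScriptPhase("chase", 0, n_chase - 1),
        ScriptPhase("overlap", n_chase, n_chase + n_overlap - 1),
        ScriptPhase("separate", n_chase + n_overlap, n_chase + n_overlap + n_sep - 1),
    )


@dataclass
class VideoScene:
    """Rendered frames plus scripted ground-truth mating intervals."""

    frames: list
    scenario: VideoScenario
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict:
        """Write zero-padded PNG frames plus a JSON sidecar with fps."""
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        width = len(str(len(self.frames) - 1))
        for i, frame in enumerate(self.frames):
            iio.imwrite(out_dir / f"frame_{i:0{width}d}.png", frame)
        meta = {"fps": self.scenario.fps, "frame_count": len(self.frames)}
        with open(out_dir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        return {"dir": out_dir, "meta": out_dir / "meta.json"}


def _ellipse_mask(shape: tuple, center: tuple, axes: tuple) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _weevil_centers(scenario: VideoScenario, rng: np.random.Generator) -> np.ndarray:
    """Per-frame centers of the two weevils, shape (n_frames, 2, 2).

    The female wanders slowly around the lower-left quadrant; the male
    trails her at a gap that shrinks during the chase, collapses to a
    small mounting offset during overlap, and reopens afterwards.
    """
    h, w = scenario.frame_size
    a_r, a_c = scenario.blob_axes
    margin = max(a_r, a_c) + 3.0
    n = scenario.n_frames
    t = np.arange(n)

    base = np.array([0.68 * h, 0.30 * w])
    female = np.stack(
        [
            base[0] + 0.08 * h * np.sin(2 * np.pi * t / (18.0 * scenario.fps)),
            base[1] + 0.10 * w * np.sin(2 * np.pi * t / (25.0 * scenario.fps) + 1.0),
        ],
        axis=1,
    )
    female += rng.normal(0.0, scenario.jitter_px, size=female.shape)

    gap_far = 6.0 * a_c
    gap_near = 2.0 * a_c + 6.0  # still two separate components
    mount_offset = np.array([-0.6 * a_r, 0.3 * a_c])  # heavy ellipse overlap

    male = np.empty_like(female)
    direction = np.array([0.0, 1.0])  # male approaches from the left
    for phase in scenario.script:
        idx = np.arange(phase.start_frame, phase.end_frame + 1)
        span = max(len(idx) - 1, 1)
        frac = (idx - phase.start_frame) / span
        if phase.phase == "chase":
            gap = gap_far + (gap_near - gap_far) * frac
            male[idx] = female[idx] - np.outer(gap, direction)
        elif phase.phase == "overlap":
            male[idx] = female[idx] + mount_offset
        else:  # separate
            gap = gap_near + (gap_far - gap_near) * frac
            male[idx] = female[idx] - np.outer(gap, direction)

    centers = np.stack([female, male], axis=1)
    centers[..., 0] = np.clip(centers[..., 0], margin, h - margin)
    centers[..., 1] = np.clip(centers[..., 1], margin, w - margin)
    return centers


def generate_video(scenario: VideoScenario) -> VideoScene:
    """Render the scripted scene; deterministic under ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.frame_size
    centers = _weevil_centers(scenario, rng)

    background = np.full((h, w), scenario.background_intensity, dtype=np.uint8)
    if scenario.include_mango:
        mango_axes = (0.16 * h, 0.20 * w)
        mango_center = (0.25 * h, 0.72 * w)
        background[_ellipse_mask((h, w), mango_center, mango_axes)] = scenario.mango_intensity

    frames = []
    for i in range(scenario.n_frames):
        frame = background.copy()
        for b in range(2):
            frame[_ellipse_mask((h, w), centers[i, b], scenario.blob_axes)] = (
                scenario.blob_intensity
            )
        frames.append(frame)

    events = [
        (phase.start_frame / scenario.fps, (phase.end_frame + 1) / scenario.fps)
        for phase in scenario.script
        if phase.phase == "overlap"
    ]
    return VideoScene(
        frames=frames, scenario=scenario, ground_truth=GroundTruth(video_events=events)
    )


def read_labels_csv(path: str | Path) -> list[dict]:
    """Read a ``segment_index,start_s,end_s,label`` file."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = []
        for row in reader:
            rows.append(
                {
                    "segment_index": int(row["segment_index"]),
                    "start_s": float(row["start_s"]),
                    "end_s": float(row["end_s"]),
                    "label": Activity(row["label"]),
                }
            )
    return rows


def read_video_dir(path: str | Path) -> tuple:
    """Load a frame directory with its JSON sidecar; returns (frames, fps)."""
    import imageio.v3 as iio

    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    frame_paths = sorted(path.glob("frame_*.png")) + sorted(path.glob("frame_*.pgm"))
    frames = [np.asarray(iio.imread(p)) for p in frame_paths]
    if len(frames) != meta["frame_count"]:
        raise ValueError(
            f"{path}: sidecar promises {meta['frame_count']} frames, found {len(frames)}"
        )
    return frames, float(meta["fps"])
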