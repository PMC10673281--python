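"""End-to-end reproducible runs: synthesis → features → SVM, video → events.

A ``RunConfig`` bundles every stage's parameters and one global seed;
per-stage seeds are derived from it by fixed offsets so each stage is
independently reproducible. Runs can emit a ``RunManifest`` listing the
config hash and a checksum for every artifact written, making reruns
verifiable byte-for-byte.

The audio pipeline mirrors the acquisition protocol: generate (or load)
a labeled recording, cut 5 s segments, RMS-normalize, extract aggregate
MFCC features, split 70/30 stratified, train the SVM and report
confusion matrices for each binary task in a validation phase and a
testing phase, plus both overall-accuracy aggregations. The validation
phase is an independent 70/30 split at a second seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio_dsp import (
    AudioSegment,
    read_wav,
    rms_normalize,
    segment,
    signal_stats,
)
from .bands import BandScheme, DEFAULT_BANDS
from .classify import (
    BINARY_TASKS,
    LabeledFeatureSet,
    SplitSpec,
    SvmParams,
    evaluate,
    make_binary,
    overall_accuracy,
    split_dataset,
    train_svm,
)
from .mfcc import MfccConfig, aggregate_features, build_filterbank, mfcc
from .synthgen import (
    AudioScenario,
    VideoScenario,
    generate_audio,
    generate_video,
    read_labels_csv,
    read_video_dir,
)
from .videoseg import VideoSegConfig, segment_mating

_SEED_MOD = 2**31

#: fixed per-stage seed offsets derived from the global seed
STAGE_SEED_OFFSETS = {"audio": 1, "split": 2, "svm": 3, "video": 4, "validation_split": 12}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + STAGE_SEED_OFFSETS[stage]) % _SEED_MOD


@dataclass
class RunConfig:
    """Fully serializable parameters of a pipeline run."""

    seed: int = 0
    audio: AudioScenario = field(default_factory=AudioScenario)
    video: VideoScenario = field(default_factory=VideoScenario)
    mfcc: MfccConfig | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    svm: SvmParams = field(default_factory=SvmParams)
    videoseg: VideoSegConfig | None = None
    bands: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        audio_seed = stage_seed(self.seed, "audio")
        if self.audio.seed != audio_seed:
            self.audio = dataclasses.replace(self.audio, seed=audio_seed)
        video_seed = stage_seed(self.seed, "video")
        if self.video.seed != video_seed:
            self.video = dataclasses.replace(self.video, seed=video_seed)
        if self.mfcc is None:
            self.mfcc = MfccConfig.for_sample_rate(self.audio.sample_rate)
        if self.split.seed != stage_seed(self.seed, "split"):
            self.split = dataclasses.replace(self.split, seed=stage_seed(self.seed, "split"))
        if self.svm.seed != stage_seed(self.seed, "svm"):
            self.svm = dataclasses.replace(self.svm, seed=stage_seed(self.seed, "svm"))
        if self.videoseg is None:
            self.videoseg = VideoSegConfig(
                expected_blob_area=self.video.blob_area,
                blob_major_axis=2.0 * max(self.video.blob_axes),
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["video"]["script"] = [
            [p.phase, p.start_frame, p.end_frame] for p in self.video.script
        ]
        d["bands"] = {a.value: list(b) for a, b in self.bands.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Checksummed record of everything a run produced."""

    config_hash: str
    version: str
    artifacts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def add_artifact(self, path: str | Path) -> None:
        path = Path(path)
        self.artifacts[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def extract_features(
    segments: list, cfg: MfccConfig, provenance: dict | None = None
) -> LabeledFeatureSet:
    """RMS-normalize each labeled segment and aggregate its MFCCs."""
    sample_rates = {s.sample_rate for s in segments}
    if len(sample_rates) != 1:
        raise ValueError("segments must share one sample rate")
    bank = build_filterbank(cfg, sample_rates.pop())
    rows, labels, ids = [], [], []
    for i, seg in enumerate(segments):
        rows.append(aggregate_features(mfcc(rms_normalize(seg), cfg, bank=bank)))
        labels.append(seg.label)
        ids.append(f"seg{i:05d}")
    return LabeledFeatureSet(
        features=np.array(rows), labels=labels, ids=ids, provenance=provenance or {}
    )


def features_from_wav(wav_path, labels_csv, cfg: MfccConfig | None = None) -> LabeledFeatureSet:
    """Build the classifier dataset from a recording plus its label file."""
    wave = read_wav(wav_path)
    if cfg is None:
        cfg = MfccConfig.for_sample_rate(wave.sample_rate)
    segments = []
    for row in read_labels_csv(labels_csv):
        i0 = int(round(row["start_s"] * wave.sample_rate))
        i1 = int(round(row["end_s"] * wave.sample_rate))
        segments.append(
            AudioSegment(
                samples=wave.samples[i0:i1],
                sample_rate=wave.sample_rate,
                offset=row["start_s"],
                label=row["label"],
            )
        )
    return extract_features(segments, cfg, provenance={"wav": str(wav_path)})


@dataclass
class AudioPipelineResult:
    """Per-task reports for both phases plus the overall accuracies."""

    reports: dict
    overall: dict
    dataset: LabeledFeatureSet

    def testing_reports(self) -> list:
        return [phases["testing"] for phases in self.reports.values()]

    def to_dict(self) -> dict:
        return {
            "tasks": {
                task: {phase: rep.to_dict() for phase, rep in phases.items()}
                for task, phases in self.reports.items()
            },
            "overall": self.overall,
        }


def run_tasks(
    dataset: LabeledFeatureSet, split: SplitSpec, svm: SvmParams,
    validation_seed: int | None = None,
) -> AudioPipelineResult:
    """Train and evaluate the three binary tasks on a feature set."""
    if validation_seed is None:
        validation_seed = (split.seed + 10) % _SEED_MOD
    reports: dict = {}
    for task in BINARY_TASKS:
        task_data = make_binary(dataset, task)
        reports[task] = {}
        for phase, split_seed in (("validation", validation_seed), ("testing", split.seed)):
            spec = dataclasses.replace(split, seed=split_seed)
            train, test = split_dataset(task_data, spec)
            model = train_svm(train, svm)
            reports[task][phase] = evaluate(model, test, phase=phase, task=task)
    testing = [phases["testing"] for phases in reports.values()]
    agg = overall_accuracy(testing)
    return AudioPipelineResult(
        reports=reports,
        overall={
            "pooled_percent": agg.pooled_percent,
            "unweighted_mean_percent": agg.unweighted_mean_percent,
        },
        dataset=dataset,
    )


def run_audio_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> AudioPipelineResult:
    """Synthesize audio, extract features, train and report all tasks."""
    t0 = time.perf_counter()
    scene = generate_audio(cfg.audio, cfg.bands)
    dataset = extract_features(
        scene.segments, cfg.mfcc,
        provenance={"scenario": "synthetic", "seed": cfg.audio.seed},
    )
    result = run_tasks(dataset, cfg.split, cfg.svm,
                       validation_seed=stage_seed(cfg.seed, "validation_split"))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__)
        paths = scene.write(out_dir)
        report_path = out_dir / "classifier_reports.json"
        with open(report_path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        for p in (*paths.values(), report_path):
            manifest.add_artifact(p)
        manifest.timings_s["audio_pipeline"] = time.perf_counter() - t0
        manifest.write(out_dir / "manifest.json")
    return result


@dataclass
class VideoPipelineResult:
    """Recovered events plus the comparison against scripted truth."""

    events: list
    ground_truth: list
    recovery: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"event_id": i, "start_s": e.start, "end_s": e.end, "duration_s": e.duration}
                for i, e in enumerate(self.events)
            ],
            columns=["event_id", "start_s", "end_s", "duration_s"],
        )


def _recovery_report(events: list, truth: list) -> list:
    report = []
    for gt_start, gt_end in truth:
        if events:
            best = min(events, key=lambda e: abs(e.start - gt_start))
            report.append(
                {
                    "gt_start_s": gt_start,
                    "gt_duration_s": gt_end - gt_start,
                    "recovered_start_s": best.start,
                    "recovered_duration_s": best.duration,
                    "start_error_s": best.start - gt_start,
                    "duration_error_s": best.duration - (gt_end - gt_start),
                }
            )
        else:
            report.append(
                {"gt_start_s": gt_start, "gt_duration_s": gt_end - gt_start,
                 "recovered_start_s": None, "recovered_duration_s": None,
                 "start_error_s": None, "duration_error_s": None}
            )
    return report


def run_video_pipeline(
    cfg: RunConfig, out_dir: str | Path | None = None, frames_dir: str | Path | None = None
) -> VideoPipelineResult:
    """Render (or load) the scene and segment mating events."""
    t0 = time.perf_counter()
    if frames_dir is not None:
        frames, fps = read_video_dir(frames_dir)
        truth = []
    else:
        scene = generate_video(cfg.video)
        frames, fps = scene.frames, cfg.video.fps
        truth = scene.ground_truth.video_events
    events = segment_mating(frames, fps, cfg.videoseg)
    result = VideoPipelineResult(
        events=events, ground_truth=truth, recovery=_recovery_report(events, truth)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        events_path = out_dir / "events.csv"
        result.to_frame().to_csv(events_path, index=False)
        manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__)
        manifest.add_artifact(events_path)
        if truth:
            recovery_path = out_dir / "recovery.json"
            with open(recovery_path, "w") as fh:
                json.dump(result.recovery, fh, indent=2)
            manifest.add_artifact(recovery_path)
        manifest.timings_s["video_pipeline"] = time.perf_counter() - t0
        manifest.write(out_dir / "manifest.json")
    return result


#: Table-style column order of the per-file statistics report
SENSOR_STATS_COLUMNS = (
    "file", "minimum", "maximum", "mean",
    "dynamic_range_db", "crest_factor_db", "autocorrelation_time_s",
)


def sensor_stats(wav_paths, seg_len: float | None = None) -> pd.DataFrame:
    """Signal statistics per file in the sensor-comparison column order.

    With ``seg_len`` set, statistics are computed on the first full
    segment; otherwise on the whole file.
    """
    rows = []
    for path in wav_paths:
        wave = read_wav(path)
        if seg_len is not None:
            segs = segment(wave, seg_len)
            if not segs:
                raise ValueError(f"{path}: shorter than one {seg_len} s segment")
            target = segs[0]
        else:
            target = AudioSegment(samples=wave.samples, sample_rate=wave.sample_rate)
        stats = signal_stats(target)
        rows.append(
            {
                "file": str(path),
                "minimum": stats.minimum,
                "maximum": stats.maximum,
                "mean": stats.mean,
                "dynamic_range_db": stats.dynamic_range_db,
                "crest_factor_db": stats.crest_factor_db,
                "autocorrelation_time_s": stats.autocorrelation_time_s,
            }
        )
    return pd.DataFrame(rows, columns=SENSOR_STATS_COLUMNS)
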