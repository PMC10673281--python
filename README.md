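# weevilsense

Acoustic activity classification and video mating-event segmentation for the
mango pulp weevil (*Sternochetus frigidus*), a quarantine pest that develops
inside mango fruit without any external sign of infestation. Because infested
fruit looks healthy, detection has to rely on what the insect *does*: the
sounds it makes while moving and the stereotyped chase-and-mount behaviour of
mating pairs. `weevilsense` is a tested, reusable implementation of that
detection pipeline for researchers in applied entomology and agricultural
acoustics, exercised end-to-end on synthetic audio and video whose statistical
structure matches the measured behaviour.

## What it computes

**Audio.** Weevil activities occupy distinct frequency bands: mating calls at
800–950 Hz, pupal movement at 1–4 kHz, adult walking at 4–5 kHz, with resting
segments carrying only background noise. A recording is cut into fixed 5 s
segments, RMS-normalized, and summarized two ways:

- *Dominant-band characterization*: the activity band holding the largest
  integrated spectral power, a transparent rule-based baseline.
- *MFCC + SVM classification*: per frame, the magnitude spectrum is pooled
  through triangular filters spaced uniformly on the Mel scale
  (`m = 2595·log10(1 + f/700)`), log-compressed and decorrelated with an
  orthonormal DCT-II; per segment, the mean and standard deviation of the
  first 13 coefficients form the feature vector. A standardized RBF-kernel SVM
  is trained on a stratified 70/30 split and reported as a confusion matrix
  with accuracy `= 100·trace/total` and error `= 100 − accuracy`, for three
  binary tasks (pupal moving vs resting, adult walking vs resting, mating vs
  non-mating) in both a validation and a testing phase.

**Video.** Mating is delimited behaviourally: each frame is binarized with
Otsu's threshold, dark weevil-sized connected components are kept by an area
window (rejecting speckle and the much larger mango region), detections are
gated by distance to the constant-velocity Kalman predictions of the two
tracks, and a mating event is a persistent run of frames in which the two
animals' boxes intersect or merge into a single blob — yielding a start
timestamp and the bout duration.

**Synthetic scenes.** Because the original recordings are not deposited, the
package ships a first-class generator: Poisson-timed noise bursts band-passed
into each activity's band at a configurable SNR, and scripted
chase → overlap → separation videos with exact ground truth (mating durations
drawn from 15–20 s, the natural 15–20 min bout at desk scale).

## Worked example

```bash
python examples/04_mating_video_segmentation.py
```

```
scripted truth : start 5.0 s, duration 19.7 s
recovered event: start 5.0 s, end 24.7 s, duration 19.7 s
```

The pipeline recovers the scripted bout exactly: the event opens at the first
of `k_persist = 3` consecutive overlap frames (5.0 s into the clip, after the
chase) and closes when the animals separate, so start and duration agree with
the script to within 2·k_persist/fps = 0.6 s. The other examples print the
signal-statistics table (a bursty segment shows a crest factor near 25 dB vs
3.01 dB for a pure sine), per-segment dominant-band recovery (12/12 at the
noise-free setting, in-band power fractions 0.96–0.98), and the per-task
classifier reports (100% test accuracy per task at 30 dB SNR on the small
example scene).

From Python:

```python
import weevilsense as ws

result = ws.run_audio_pipeline(ws.RunConfig(seed=7))
print(result.overall)          # {'pooled_percent': ..., 'unweighted_mean_percent': ...}

events = ws.segment_mating(frames, fps=10.0,
                           config=ws.VideoSegConfig(expected_blob_area=264.0))
```

A thin CLI mirrors the pipelines (`weevilsense synth-audio | synth-video |
features | train | evaluate | segment-mating | sensor-stats | run-all`).

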