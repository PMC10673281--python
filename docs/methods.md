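# Methods

## Problem and scope

`weevilsense` implements two complementary detectors for mango pulp weevil
(MPW) behaviour: an acoustic activity classifier over fixed-length audio
segments, and a video segmenter that timestamps mating bouts from the
overlap of two tracked animals. The measured biology the package encodes is
the band placement of each activity — mating 800–950 Hz, pupal movement
1–4 kHz, adult walking 4–5 kHz — and the 15–20 minute duration of a mating
bout. Everything else (burst shapes, filter settings, tracker gains) is an
engineering choice documented below. Hardware concerns (sensor selection,
chamber acoustics, temperature control) are out of scope.

## Synthetic scenes

No public recordings of MPW activity exist, so the generator is a first-class
module with exact ground truth rather than a test fixture.

**Audio model.** A non-resting segment is a Poisson-timed train (default
8 events/s) of 5–20 ms Hann-enveloped white-noise bursts, band-passed into
the activity's band with an order-4 zero-phase Butterworth filter (applied
forward-backward, so the effective magnitude response is order 8 and no phase
distortion is introduced), then normalized to unit RMS. This emulates the
impulsive character of insect-produced sound while guaranteeing the one
property that is actually measured — band confinement: ≥ 96% of segment power
falls inside the generating band at the noise-free setting, comfortably above
the 95% contract. White Gaussian noise is added at
`snr_db = 10·log10(P_signal/P_noise)` computed over the whole segment.

*Resting* segments are unit-RMS white noise at every SNR: resting **is** the
background-noise class, so its content should not depend on the SNR knob,
which scales only the noise mixed into band-signal segments. This also keeps
the noise-free scenario well-defined (a silent resting class would make RMS
normalization and log-energies degenerate). A consequence worth knowing: the
four SNR settings generated from the same seed share identical burst signals
and identically shaped noise (only rescaled), which makes accuracy-vs-SNR
comparisons paired rather than independent.

Defaults are the study conditions: 44.1 kHz sampling (the 4–5 kHz band needs
headroom below Nyquist; 44.1 kHz is the audio-hardware standard), 5 s
segments, and 16-bit PCM WAV output with a 0.05 master gain so burst peaks
(crest factors ≈ 25 dB) never clip. Labels are written as
`segment_index,start_s,end_s,label` CSV.

**Video model.** 8-bit grayscale frames (240×320 default) with background
intensity 220, two weevils as dark (40) ellipses of semi-axes 7×12 px
(area ≈ 264 px²), and an optional static mango ellipse at intensity 90 about
30× the weevil area. The behavioural script is a contiguous sequence of
chase / overlap / separate phases; during the chase the male trails the
female with a shrinking gap (always ≥ 2 ellipse widths + 6 px, so the
animals remain separate components), during overlap he sits at a small
mounting offset so the two ellipses merge into one connected component, and
during separation the gap reopens. Mating durations are drawn uniformly from
15–20 s at 10 fps — the natural 15–20 min bout compressed ~60× to desk scale,
preserving the ratio of bout length to frame period that the event logic
actually sees. Ground truth is the overlap phase converted to seconds.

**What the generator does not emulate.** Real recordings contain sensor
transfer functions, reverberation, non-stationary background noise, and
overlapping activities; real footage has lighting gradients, shadows,
occlusion by the mango, and animals of unequal size. Passing tests therefore
demonstrate that the pipeline recovers what it is designed to recover under
its stated signal model, not that the printed accuracies transfer to field
recordings.

## Audio front-end

Segmentation is non-overlapping (no hop is defined for the 5 s windows; any
overlap choice would be an invention) and a trailing partial segment is
dropped. RMS normalization scales each segment to unit RMS and is undefined
(an error) for all-zero input.

The plain spectrum used for band characterization is the unwindowed one-sided
FFT magnitude, which keeps Parseval's identity exact and testable; the MFCC
path applies its own window. Signal statistics follow standard definitions,
since the originals were produced by an audio-analysis GUI whose formulas are
not recoverable: crest factor `20·log10(peak/RMS)`; dynamic range
`20·log10(max|q|/min nonzero |q|)` after 16-bit quantization (the smallest
amplitude the recording chain resolves); autocorrelation time the smallest
positive lag at which the normalized autocorrelation magnitude first falls
below 0.1 (threshold chosen here; only a time value is conventionally
reported, never a formula).

`dominant_band` integrates one-sided spectral power over each activity band
and returns the argmax, reporting the out-of-band fraction separately. The
rule-based baseline classifier calls a segment resting unless the best
band's power *density* exceeds twice the segment's average spectral density
— white noise sits at a density ratio of ~1 regardless of level, so the
threshold separates "noise floor" from "band emission" without an absolute
power calibration.

## MFCC

All parameters are conventional speech-processing defaults, stated because
the original front-end's settings are unknown: 25 ms frames, 10 ms hop,
periodic Hamming window, FFT size the next power of two above the frame,
26 triangular filters uniform on the Mel scale (`2595·log10(1 + f/700)`)
between 0 Hz and Nyquist, power spectrum into the bank, log with floor
1e-10 (the floor makes all-zero input well-defined and bounds the dynamic
range of the log), orthonormal DCT-II, 13 coefficients kept. Filter edges are
evaluated at the true FFT bin frequencies rather than snapped to bins; a bank
too dense for the FFT resolution (a filter covering no bin, or two filters
peaking on the same bin) is rejected at construction.

Per-segment features are the mean and standard deviation of each coefficient
across frames (a 26-vector): the aggregation is unstated in the source
protocol, and mean+std is the simplest summary that captures both the
spectral envelope and its variability; delta coefficients and liftering are
deliberately omitted.

## Classification

Three binary tasks mirror the three reported experiments — pupal moving vs
resting, adult walking vs resting, mating vs non-mating (all other classes
pooled) — with a 4-class mode available through the same API. The 70/30
split is stratified per class with largest-remainder rounding (so per-class
train counts sum to the rounded global 70%) and a seeded shuffle.

The SVM is an RBF kernel with C = 1; the inverse bandwidth is set by the
median heuristic, `gamma = 1/median(pairwise squared distance)` on the
standardized training features (subsampled to 500 rows), a parameter-free
default that adapts to the feature scale. Features are standardized with
train-set statistics stored in the model. No class weighting, calibration or
hyperparameter search: the evaluation surface is raw accuracy, matching the
reporting style being reproduced.

The *validation* phase is an independent 70/30 split at a second seed
(train + evaluate repeated), the *testing* phase the split at the primary
seed; the two phases are procedurally identical, which is the plainest
reading of a validation/testing pair that is never defined. Overall accuracy
across tasks is reported under both defensible aggregations — pooled counts
(`100·Σtrace/Σtotal`) and the unweighted mean of per-task accuracies — since
no aggregation rule is stated and the printed per-task numbers reproduce
neither uniquely.

## Video segmentation

Otsu's threshold maximizes the between-class variance of the 256-bin
histogram over the split `{x < t}` vs `{x ≥ t}`, scanning all 256 candidates
and returning the smallest maximizer; foreground is then `x < t` (dark
animals on a light scene), so the convention is self-consistent. Components
are 8-connected; the area window defaults to 0.5–3× the expected
single-weevil area, chosen so a merged mating pair (≤ 2× one animal) stays
in-window while the mango region (~30×) is rejected.

Tracking uses one constant-velocity Kalman filter per animal: state
(row, col, v_row, v_col), process and measurement noise 1 px, initial
covariance 10·I, initialized at the first unassigned detection with zero
velocity. The innovation covariance is inverted with a pseudo-inverse so the
noise-free limit (both noises zero) stays well-defined: once the state is
fully determined the covariance and gain collapse exactly to zero.
Detections are assigned to tracks by minimum-total-distance assignment
(Hungarian; optimal and equal to brute force for the two-track case) with
candidates farther than `max_jump` (default 5× the blob major axis) from
every prediction rejected as spurious — the animals cannot jump across the
arena between adjacent frames. "Training" a Kalman filter, as the procedure
is sometimes described, is interpreted here as parameter configuration; there
is no learning loop.

When two tracks are active and exactly one in-window blob remains, the
animals have merged: both tracks update against the merged centroid and the
frame is flagged as overlapping; otherwise the flag is the intersection test
on the two tracks' boxes (last blob extents re-centered on the current state).
Events are runs of ≥ `k_persist` = 3 consecutive flagged frames, closed by
≥ 3 clear frames; the persistence rule suppresses single-frame flicker at the
cost of a bounded ±2·k_persist/fps (0.6 s at 10 fps) timing uncertainty,
which is the tolerance used in the recovery checks. An event still open at
the last frame is closed there. If fewer than two animals are ever tracked
the result is an empty list with a warning, not an error.

## Pipelines, seeds, problem sizes

One global seed derives per-stage seeds by fixed offsets (audio +1, split +2,
SVM +3, video +4, validation split +12, modulo 2³¹), so any stage can be
re-run in isolation and a persisted `RunConfig` reproduces every artifact
byte-for-byte; the manifest records a SHA-256 per output file and of the
canonical config JSON.

Verification runs use 200 segments per class at 44.1 kHz for the audio
claims (600 band-labeled segments; three tasks of 400–800 segments each) and
20 scripted videos plus 5 event-free controls for the video claims — sizes
at which the checked properties are stable while a full run completes in
minutes on one CPU. The tests' fixed seeds are arbitrary constants.

## Known limitations

- The synthetic SNR sweep is paired by construction (shared seed), so
  accuracy-vs-SNR monotonicity is evaluated under coupled noise, not
  independent replicates.
- Band separability makes the synthetic classification task easy (accuracies
  saturate near 100% at moderate SNR); the pipeline's value is the tested
  machinery, not a claim about field accuracy.
- The video segmenter assumes exactly one pair of similar-sized animals,
  stable illumination, and a static scene; multi-pair scenes and sex
  identification are out of scope.
- The mating-band audio classifier and the video segmenter are not coupled:
  recovered video events can be used to label audio segments via the label
  CSV, but no automatic audio-video fusion is implemented.
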