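"""Video mating-event segmentation: Otsu, blob tracking, overlap timestamps.

The pipeline follows the classical recipe for tracking two dark animals
on a light background: binarize each frame with Otsu's threshold, keep
8-connected components whose pixel area falls inside a weevil-sized
window (rejecting speckle and the much larger mango region), gate
candidate detections by how far they sit from the constant-velocity
Kalman predictions (weevils cannot teleport between adjacent frames),
and track both animals. A frame is flagged as "overlapping" when the
two tracks' boxes intersect or when the two animals have merged into a
single in-window blob; a run of at least ``k_persist`` flagged frames
opens a mating event and a run of at least ``k_persist`` clear frames
closes it, yielding start/end timestamps and the bout duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Blob:
    """A connected foreground component.

    Boxes are half-open ``[top, bottom) x [left, right)`` in 0-based
    (row, col) coordinates with the origin at the top-left.
    """

    area: int
    centroid: tuple
    bbox: tuple

    def __post_init__(self) -> None:
        top, left, bottom, right = self.bbox
        if self.area <= 0:
            raise ValueError("blob area must be positive")
        if not (top <= self.centroid[0] < bottom and left <= self.centroid[1] < right):
            raise ValueError("centroid must lie inside the bounding box")


def otsu_threshold(frame: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram of an 8-bit frame.

    Returns the smallest t in [0, 255] maximizing the between-class
    variance of the split {x < t} vs {x >= t}.
    """
    frame = np.asarray(frame)
    hist = np.bincount(frame.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold is undefined for a constant frame")
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    mu_total = float(np.sum(levels * p))

    # cumulative weight/mean of the lower class {x < t} for t = 0..255
    w_low = np.concatenate([[0.0], np.cumsum(p)[:-1]])
    mu_low_sum = np.concatenate([[0.0], np.cumsum(levels * p)[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        between = np.where(
            (w_low > 0) & (w_low < 1),
            (mu_total * w_low - mu_low_sum) ** 2 / (w_low * (1.0 - w_low)),
            0.0,
        )
    return int(np.argmax(between))  # argmax returns the smallest maximizer


def detect_blobs(frame: np.ndarray, threshold: float, area_window: tuple) -> list:
    """Weevil-sized dark components: foreground = intensity < threshold.

    8-connected components with area outside ``area_window`` (min, max)
    are discarded; survivors are sorted by area, largest first.
    """
    lo, hi = area_window
    foreground = np.asarray(frame) < threshold
    labeled, n = ndimage.label(foreground, structure=EIGHT_CONNECTED)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    blobs = []
    for lab, area in zip(range(1, n + 1), areas):
        if not lo <= area <= hi:
            continue
        rows, cols = np.nonzero(labeled == lab)
        blobs.append(
            Blob(
                area=int(area),
                centroid=(float(rows.mean()), float(cols.mean())),
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
            )
        )
    return sorted(blobs, key=lambda b: -b.area)


def overlap(box_a: tuple, box_b: tuple) -> tuple:
    """Whether two half-open boxes intersect, plus their IoU.

    Touching edges do not count as overlap under the half-open
    convention.
    """
    for box in (box_a, box_b):
        top, left, bottom, right = box
        if bottom <= top or right <= left:
            raise ValueError(f"degenerate box {box}")
    inter_h = min(box_a[2], box_b[2]) - max(box_a[0], box_b[0])
    inter_w = min(box_a[3], box_b[3]) - max(box_a[1], box_b[1])
    inter = max(inter_h, 0) * max(inter_w, 0)
    area = lambda b: (b[2] - b[0]) * (b[3] - b[1])
    union = area(box_a) + area(box_b) - inter
    return inter > 0, inter / union


@dataclass
class KalmanTrack:
    """Constant-velocity Kalman track of one weevil.

    State is (row, col, v_row, v_col) in pixels and pixels/frame.
    """

    track_id: int
    state: np.ndarray
    covariance: np.ndarray
    process_noise: float = 1.0
    measurement_noise: float = 1.0
    last_blob: Blob | None = None
    misses: int = 0

    F = np.array(
        [[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]]
    )
    H = np.array([[1.0, 0, 0, 0], [0, 1, 0, 0]])

    @classmethod
    def from_detection(
        cls, track_id: int, blob: Blob, initial_cov: float = 10.0, **kwargs
    ) -> "KalmanTrack":
        state = np.array([blob.centroid[0], blob.centroid[1], 0.0, 0.0])
        return cls(
            track_id=track_id,
            state=state,
            covariance=initial_cov * np.eye(4),
            last_blob=blob,
            **kwargs,
        )

    @property
    def position(self) -> np.ndarray:
        return self.state[:2]

    def predicted_position(self) -> np.ndarray:
        return (self.F @ self.state)[:2]

    def step(self, measurement=None) -> None:
        """Predict, then update if a centroid measurement is available."""
        q = self.process_noise**2
        self.state = self.F @ self.state
        self.covariance = self.F @ self.covariance @ self.F.T + q * np.eye(4)
        if measurement is None:
            self.misses += 1
            return
        z = np.asarray(measurement, dtype=np.float64)
        if not np.all(np.isfinite(z)):
            raise ValueError("measurement must be finite")
        r = self.measurement_noise**2
        innovation = z - self.H @ self.state
        s = self.H @ self.covariance @ self.H.T + r * np.eye(2)
        # pinv keeps the noise-free case well-defined: once the state is
        # fully determined the covariance (and gain) are exactly zero
        gain = self.covariance @ self.H.T @ np.linalg.pinv(s)
        self.state = self.state + gain @ innovation
        self.covariance = (np.eye(4) - gain @ self.H) @ self.covariance
        self.misses = 0

    def current_box(self) -> tuple | None:
        """Last blob's box re-centered on the current state position."""
        if self.last_blob is None:
            return None
        top, left, bottom, right = self.last_blob.bbox
        half_h, half_w = (bottom - top) / 2.0, (right - left) / 2.0
        r, c = self.position
        return (r - half_h, c - half_w, r + half_h, c + half_w)


def kalman_step(track: KalmanTrack, measurement=None) -> KalmanTrack:
    """Functional wrapper: one predict(+update) cycle, returning the track."""
    track.step(measurement)
    return track


def gate_by_distance(tracks: list, candidates: list, max_jump: float) -> tuple:
    """Assign detections to tracks; reject candidates too far from all.

    Assignment minimizes the total track-to-candidate distance
    (optimal for the two-weevil case); any candidate farther than
    ``max_jump`` from every track prediction is flagged spurious.
    Returns ``(assignments, rejected)`` where assignments maps
    track_id -> candidate index.
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be positive")
    if not tracks or not candidates:
        return {}, list(range(len(candidates)))
    predictions = np.array([t.predicted_position() for t in tracks])
    centroids = np.array([b.centroid for b in candidates])
    dist = np.linalg.norm(predictions[:, None, :] - centroids[None, :, :], axis=-1)
    cost = np.where(dist <= max_jump, dist, 1e9)
    rows, cols = linear_sum_assignment(cost)
    assignments = {
        tracks[r].track_id: int(c) for r, c in zip(rows, cols) if dist[r, c] <= max_jump
    }
    rejected = [
        j for j in range(len(candidates))
        if j not in assignments.values() and np.all(dist[:, j] > max_jump)
    ]
    return assignments, rejected


@dataclass(frozen=True)
class MatingEvent:
    """An overlap-delimited bout with start/end timestamps in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class VideoSegConfig:
    """Tuning knobs of the event-segmentation pipeline.

    ``expected_blob_area`` is the single-weevil pixel area; the area
    window spans 0.5x to 3x of it so a merged mating pair stays
    in-window. ``max_jump`` defaults to 5x the blob major axis.
    """

    expected_blob_area: float
    area_window_factors: tuple = (0.5, 3.0)
    max_jump: float | None = None
    blob_major_axis: float | None = None
    k_persist: int = 3
    process_noise: float = 1.0
    measurement_noise: float = 1.0

    def area_window(self) -> tuple:
        lo, hi = self.area_window_factors
        return (lo * self.expected_blob_area, hi * self.expected_blob_area)

    def resolved_max_jump(self) -> float:
        if self.max_jump is not None:
            return self.max_jump
        major = self.blob_major_axis
        if major is None:
            # fall back to the major axis of a 2:1 ellipse of the expected area
            major = 2.0 * np.sqrt(2.0 * self.expected_blob_area / np.pi)
        return 5.0 * major


@dataclass
class FrameDebug:
    """Per-frame diagnostics emitted alongside the event list."""

    frame: int
    threshold: int
    n_blobs: int
    overlap_flag: bool


def _runs_to_events(flags: list, fps: float, k_persist: int) -> list:
    """Turn the per-frame overlap flags into persistent events."""
    events = []
    start = None
    run_true = run_false = 0
    for i, flag in enumerate(flags):
        if flag:
            run_true += 1
            run_false = 0
            if start is None and run_true >= k_persist:
                start = i - k_persist + 1
        else:
            run_false += 1
            run_true = 0
            if start is not None and run_false >= k_persist:
                end = i - k_persist + 1
                events.append(MatingEvent(start=start / fps, end=end / fps))
                start = None
    if start is not None:
        events.append(MatingEvent(start=start / fps, end=len(flags) / fps))
    return events


def segment_mating(frames, fps: float, config: VideoSegConfig, collect_debug: bool = False):
    """Recover mating events from a frame sequence.

    Per frame: Otsu threshold → area-window blob detection → distance
    gating against the two Kalman tracks → track update. The overlap
    flag is raised when the tracks' boxes intersect or when exactly one
    in-window blob remains while both tracks are active (the merged
    pair). Events are runs of >= ``k_persist`` flagged frames, closed by
    runs of >= ``k_persist`` clear frames.

    Returns the event list, or ``(events, debug)`` with per-frame
    diagnostics when ``collect_debug`` is set.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    area_window = config.area_window()
    max_jump = config.resolved_max_jump()
    kwargs = dict(
        process_noise=config.process_noise, measurement_noise=config.measurement_noise
    )

    tracks: list = []
    next_id = 0
    max_tracks_seen = 0
    flags, debug = [], []
    for i, frame in enumerate(frames):
        threshold = otsu_threshold(frame)
        blobs = detect_blobs(frame, threshold, area_window)
        assignments, _rejected = gate_by_distance(tracks, blobs, max_jump)

        merged = len(tracks) == 2 and len(blobs) == 1
        if merged:
            # both animals coast on their predictions but share the one
            # merged detection, keeping both tracks alive through the bout
            for track in tracks:
                track.step(blobs[0].centroid)
                track.last_blob = blobs[0]
        else:
            for track in tracks:
                j = assignments.get(track.track_id)
                track.step(blobs[j].centroid if j is not None else None)
                if j is not None:
                    track.last_blob = blobs[j]
            assigned = set(assignments.values())
            for j, blob in enumerate(blobs):
                if j not in assigned and len(tracks) < 2:
                    tracks.append(
                        KalmanTrack.from_detection(next_id, blob, **kwargs)
                    )
                    next_id += 1
        max_tracks_seen = max(max_tracks_seen, len(tracks))

        flag = False
        if len(tracks) == 2:
            if merged:
                flag = True
            else:
                box_a, box_b = tracks[0].current_box(), tracks[1].current_box()
                if box_a is not None and box_b is not None:
                    flag, _ = overlap(box_a, box_b)
        flags.append(flag)
        if collect_debug:
            debug.append(
                FrameDebug(frame=i, threshold=threshold, n_blobs=len(blobs), overlap_flag=flag)
            )

    if max_tracks_seen < 2:
        warnings.warn("fewer than 2 weevils were ever tracked; no events can be segmented")
        events = []
    else:
        events = _runs_to_events(flags, fps, config.k_persist)
    return (events, debug) if collect_debug else events
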