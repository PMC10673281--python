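"""Otsu thresholding, blob detection, gating, Kalman tracking, events."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import weevilsense as ws
from weevilsense.videoseg import Blob, _runs_to_events


def brute_force_otsu(frame):
    """Exhaustive 256-candidate search, written independently."""
    values = np.asarray(frame).ravel()
    best_t, best_var = 0, -1.0
    for t in range(256):
        low = values[values < t]
        high = values[values >= t]
        if len(low) == 0 or len(high) == 0:
            var = 0.0
        else:
            w0 = len(low) / len(values)
            var = w0 * (1 - w0) * (low.mean() - high.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def _blob(centroid, half=5):
    r, c = centroid
    return Blob(
        area=(2 * half) ** 2,
        centroid=(float(r), float(c)),
        bbox=(int(r - half), int(c - half), int(r + half), int(c + half)),
    )


class TestOtsu:
    def test_bimodal_frame_separates_modes(self):
        frame = np.concatenate([np.full(50, 50), np.full(50, 200)]).reshape(10, 10)
        t = ws.otsu_threshold(frame)
        assert 50 < t <= 200
        assert np.array_equal(frame < t, frame == 50)

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            frame = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            assert ws.otsu_threshold(frame) == brute_force_otsu(frame)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 255), min_size=4, max_size=40))
    def test_property_matches_brute_force(self, values):
        frame = np.array(values, dtype=np.uint8)
        if len(set(values)) < 2:
            frame[0] = (int(frame[0]) + 1) % 256
        assert ws.otsu_threshold(frame) == brute_force_otsu(frame)

    def test_inversion_maps_optimum_consistently(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            frame = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
            inverted = (255 - frame).astype(np.uint8)
            assert ws.otsu_threshold(inverted) == brute_force_otsu(inverted)

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError):
            ws.otsu_threshold(np.full((5, 5), 7, dtype=np.uint8))


class TestDetectBlobs:
    def test_chase_frame_two_blobs_mango_rejected(self, short_video_scene, video_config):
        frame = short_video_scene.frames[5]
        t = ws.otsu_threshold(frame)
        blobs = ws.detect_blobs(frame, t, video_config.area_window())
        assert len(blobs) == 2
        # the mango region is foreground but far above the area window
        n_foreground = int((frame < t).sum())
        assert n_foreground > sum(b.area for b in blobs)

    def test_overlap_frame_single_blob(self, short_video_scene, video_config):
        frame = short_video_scene.frames[70]
        blobs = ws.detect_blobs(frame, ws.otsu_threshold(frame), video_config.area_window())
        assert len(blobs) == 1

    def test_blank_frame_empty_list(self):
        frame = np.full((20, 20), 200, dtype=np.uint8)
        assert ws.detect_blobs(frame, 100, (1, 50)) == []

    def test_blobs_sorted_by_area_descending(self, short_video_scene, video_config):
        frame = short_video_scene.frames[5]
        blobs = ws.detect_blobs(frame, ws.otsu_threshold(frame), video_config.area_window())
        areas = [b.area for b in blobs]
        assert areas == sorted(areas, reverse=True)


class TestOverlap:
    def test_partial_overlap_iou(self):
        hit, iou = ws.overlap((0, 0, 10, 10), (5, 5, 15, 15))
        assert hit and iou == pytest.approx(25 / 175)

    def test_touching_edges_do_not_overlap(self):
        hit, iou = ws.overlap((0, 0, 10, 10), (0, 10, 10, 20))
        assert not hit and iou == 0.0

    def test_identical_boxes(self):
        hit, iou = ws.overlap((2, 3, 8, 9), (2, 3, 8, 9))
        assert hit and iou == 1.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            ws.overlap((0, 0, 0, 10), (0, 0, 5, 5))


class TestGating:
    def _track(self, tid, position):
        blob = _blob(position)
        return ws.KalmanTrack.from_detection(tid, blob)

    def test_zero_distance_candidate_accepted(self):
        tracks = [self._track(0, (50, 50))]
        assignments, rejected = ws.gate_by_distance(tracks, [_blob((50, 50))], max_jump=10)
        assert assignments == {0: 0} and rejected == []

    def test_far_candidate_rejected(self):
        tracks = [self._track(0, (50, 50))]
        assignments, rejected = ws.gate_by_distance(tracks, [_blob((120, 120))], max_jump=10)
        assert assignments == {} and rejected == [0]

    def test_two_by_two_matches_brute_force(self):
        # greedy nearest-neighbour would pick (t0,c0)+(t1,c1) = 1 + 100;
        # the optimal pairing crosses over
        tracks = [self._track(0, (0, 0)), self._track(1, (0, 10))]
        candidates = [_blob((20, 0.0)), _blob((20, 10))]
        d = np.array(
            [
                [np.hypot(20, 0), np.hypot(20, 10)],
                [np.hypot(20, 10), np.hypot(20, 0)],
            ]
        )
        best = min(
            [({0: 0, 1: 1}, d[0, 0] + d[1, 1]), ({0: 1, 1: 0}, d[0, 1] + d[1, 0])],
            key=lambda kv: kv[1],
        )[0]
        assignments, _ = ws.gate_by_distance(tracks, candidates, max_jump=50)
        assert assignments == best


class TestKalman:
    def test_noise_free_line_recovered_exactly(self):
        start = np.array([10.0, 20.0])
        velocity = np.array([1.5, -0.75])
        blob = _blob(start, half=3)
        track = ws.KalmanTrack.from_detection(0, blob, process_noise=0.0,
                                              measurement_noise=0.0)
        for i in range(1, 12):
            ws.kalman_step(track, start + i * velocity)
        assert np.allclose(track.position, start + 11 * velocity, atol=1e-9)
        assert np.allclose(track.state[2:], velocity, atol=1e-9)

    def test_repeated_identical_measurements_converge(self):
        track = ws.KalmanTrack.from_detection(0, _blob((0, 0)), measurement_noise=0.0)
        for _ in range(5):
            ws.kalman_step(track, (5.0, 5.0))
        assert np.allclose(track.position, (5.0, 5.0), atol=1e-6)

    def test_missing_measurement_advances_by_velocity(self):
        track = ws.KalmanTrack.from_detection(0, _blob((10, 10)))
        track.state = np.array([10.0, 10.0, 2.0, -1.0])
        ws.kalman_step(track, None)
        assert np.array_equal(track.position, [12.0, 9.0])
        assert track.misses == 1

    def test_non_finite_measurement_rejected(self):
        track = ws.KalmanTrack.from_detection(0, _blob((10, 10)))
        with pytest.raises(ValueError):
            ws.kalman_step(track, (np.nan, 1.0))


class TestEvents:
    def test_scripted_event_recovered(self, short_video_scene, video_config):
        events = ws.segment_mating(short_video_scene.frames, 10.0, video_config)
        assert len(events) == 1
        (event,) = events
        gt_start, gt_end = short_video_scene.ground_truth.video_events[0]
        tol = 2 * video_config.k_persist / 10.0
        assert event.start == pytest.approx(gt_start, abs=tol)
        assert event.duration == pytest.approx(gt_end - gt_start, abs=tol)

    def test_no_overlap_script_gives_no_events(self, video_config):
        scenario = ws.VideoScenario(
            script=(ws.ScriptPhase("chase", 0, 39), ws.ScriptPhase("separate", 40, 79)),
            seed=4,
        )
        scene = ws.generate_video(scenario)
        assert ws.segment_mating(scene.frames, 10.0, video_config) == []

    def test_single_frame_flicker_suppressed(self):
        flags = [False] * 10 + [True] + [False] * 10
        assert _runs_to_events(flags, 10.0, k_persist=3) == []

    def test_persistent_run_delimited_exactly(self):
        flags = [False] * 100 + [True] * 100 + [False] * 100
        events = _runs_to_events(flags, 10.0, k_persist=3)
        assert len(events) == 1
        assert events[0].start == pytest.approx(10.0)
        assert events[0].duration == pytest.approx(10.0)

    def test_events_ordered_and_bounded(self):
        rng = np.random.default_rng(0)
        flags = list(rng.random(300) < 0.5)
        events = _runs_to_events(flags, 10.0, k_persist=3)
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start
        assert sum(e.duration for e in events) <= len(flags) / 10.0

    def test_single_blob_video_warns_and_returns_empty(self, video_config):
        frames = []
        for i in range(20):
            frame = np.full((60, 60), 220, dtype=np.uint8)
            frame[20:28, 20 + i : 28 + i] = 40
            frames.append(frame)
        with pytest.warns(UserWarning):
            events = ws.segment_mating(frames, 10.0, video_config)
        assert events == []
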