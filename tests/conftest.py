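import numpy as np
import pytest

import weevilsense as ws

#: compact sample rate for unit tests; still >2x the highest band edge
UNIT_SR = 16000.0


@pytest.fixture(scope="session")
def small_audio_scene():
    """6 segments/class at 30 dB SNR, 16 kHz, 2 s segments."""
    scenario = ws.AudioScenario(
        sample_rate=UNIT_SR, segment_length=2.0, segments_per_class=6, snr_db=30.0, seed=11
    )
    return ws.generate_audio(scenario)


@pytest.fixture(scope="session")
def small_feature_set(small_audio_scene):
    cfg = ws.MfccConfig.for_sample_rate(UNIT_SR)
    return ws.extract_features(small_audio_scene.segments, cfg)


@pytest.fixture(scope="session")
def short_video_scene():
    """Chase 3 s, overlap 8 s, separate 3 s at 10 fps."""
    script = (
        ws.ScriptPhase("chase", 0, 29),
        ws.ScriptPhase("overlap", 30, 109),
        ws.ScriptPhase("separate", 110, 139),
    )
    return ws.generate_video(ws.VideoScenario(script=script, seed=21))


@pytest.fixture
def video_config(short_video_scene):
    scen = short_video_scene.scenario
    return ws.VideoSegConfig(
        expected_blob_area=scen.blob_area, blob_major_axis=2.0 * max(scen.blob_axes)
    )


def sine_segment(freq, sr=UNIT_SR, duration=1.0, amplitude=1.0, label=None):
    t = np.arange(int(duration * sr)) / sr
    return ws.AudioSegment(
        samples=amplitude * np.sin(2 * np.pi * freq * t), sample_rate=sr, label=label
    )
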