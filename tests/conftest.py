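"""Shared fixtures: small rendered scenes reused across test modules.

Rendering is the expensive part of the suite, so the standard noiseless
recording (12 BPM, 60 s, 30 fps on a quarter-size frame) is rendered
once per session and shared read-only.
"""

import numpy as np
import pytest

from depthresp.config import RunConfig
from depthresp.simulate import (
    BreathingProgram,
    NoiseModel,
    TorsoScene,
    render_sequence,
    synth_reference_trace,
)


@pytest.fixture(scope="session")
def small_scene() -> TorsoScene:
    return TorsoScene.scaled(212, 256)


@pytest.fixture(scope="session")
def noiseless_recording(small_scene):
    """(seq, truth): 12 BPM, 60 s, 30 fps, no sensor noise."""
    program = BreathingProgram(rr_bpm=12.0, duration_s=60.0)
    return render_sequence(small_scene, program, NoiseModel.NONE, fps=30.0)


@pytest.fixture(scope="session")
def noiseless_reference(noiseless_recording):
    _, truth = noiseless_recording
    return synth_reference_trace(truth, sample_rate=100.0, trigger_lag_s=1.7)


@pytest.fixture(scope="session")
def short_recording(small_scene):
    """Cheap 10 s noiseless clip for geometry/IO tests."""
    program = BreathingProgram(rr_bpm=15.0, duration_s=10.0)
    return render_sequence(small_scene, program, NoiseModel.NONE, fps=15.0)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
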