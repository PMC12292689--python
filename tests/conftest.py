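"""Shared fixtures: synthetic recordings and tensors built at test time."""

import numpy as np
import pytest

from pianorehab import synthgen, tfr


@pytest.fixture(scope="session")
def synergy_truth():
    """Identifiable 3-synergy ground truth on 4 channels, 3 s at 400 Hz."""
    truth = synthgen.SynergyGroundTruth.random(
        rank=3, channels=4, samples=1200, fs=400.0, seed=7
    )
    env = truth.muscle_weights @ truth.activations
    truth.noise_sd = float(np.sqrt(0.05 * np.mean(env**2)))
    return truth


@pytest.fixture(scope="session")
def synergy_recording(synergy_truth):
    return synthgen.generate_synergy_emg(synergy_truth, fs=400.0)


@pytest.fixture(scope="session")
def synergy_tensor(synergy_recording):
    return tfr.build_emg_tensor(synergy_recording, tfr.WaveletConfig())


@pytest.fixture(scope="session")
def fatigue_session():
    """Default-ramp fatigue session, shortened to 60 s for test speed."""
    program = synthgen.FatigueProgram(duration_s=60.0, seed=11)
    rec, level = synthgen.generate_fatigue_emg(program, channels=4, fs=400.0)
    return rec, level
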