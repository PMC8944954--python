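import numpy as np
import pytest

from lognstim import synth

MATCHED_STUDY_PAIRS = [(1.09, 1.22), (1.23, 1.22), (0.65, 1.15),
                (0.59, 1.13), (1.35, 1.31), (0.92, 1.28)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """60-s two-channel synthetic recording with ground truth (2 kHz)."""
    params = synth.SynthesisParams(duration=60.0, seed=11,
                                   ictal_mean_interval=30.0,
                                   ictal_mean_duration=8.0)
    traces, truth = synth.synthesize(params)
    return params, traces, truth


@pytest.fixture(scope="session")
def interictal_recording():
    """120-s recording with fast events only (no ictal windows)."""
    params = synth.SynthesisParams(duration=120.0, seed=21,
                                   ictal_mean_interval=10_000.0,
                                   ictal_mean_duration=40.0,
                                   slow_rate=1e-9)
    traces, truth = synth.synthesize(params)
    return params, traces, truth
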