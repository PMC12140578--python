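import numpy as np
import pytest

from icnet import CouplingEdge, CouplingSpec, ScoutRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_recording(rng):
    """60 s of independent white noise over 4 scouts, no eye annotations."""
    return ScoutRecording(
        data=rng.standard_normal((4, 250 * 60)),
        fs=250.0,
        scout_names=["a", "b", "c", "d"],
    )


def sinusoid_pair_recording(
    f0: float = 10.0,
    fs: float = 250.0,
    duration: float = 60.0,
    shift_s: float = 0.025,
    noise_sd: float = 0.1,
    seed: int = 7,
) -> ScoutRecording:
    """Two scouts: a noisy sinusoid and a time-shifted copy of it."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * duration)) / fs
    x = np.sin(2 * np.pi * f0 * t)
    y = np.sin(2 * np.pi * f0 * (t - shift_s))
    data = np.vstack([x, y]) + noise_sd * rng.standard_normal((2, t.size))
    return ScoutRecording(data=data, fs=fs, scout_names=["x", "y"])


@pytest.fixture
def lagged_alpha_recording():
    """8 scouts with one strong quarter-cycle-lagged 10 Hz coupling (0-1)."""
    from icnet import gen_scout_signals

    spec = CouplingSpec(edges=[CouplingEdge(0, 1, 10.0, 0.9, np.pi / 2)])
    return gen_scout_signals(spec, 8, 250.0, 60.0, seed=42, eye_block_s=10.0)
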