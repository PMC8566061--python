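import numpy as np
import pytest

from fixmodal.io_gaze import GazeRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(x, y, tx=None, ty=None, **kw) -> GazeRecording:
    """Build a recording from position arrays with default zero targets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    return GazeRecording(
        t=np.arange(n, dtype=float),
        x=x,
        y=y,
        tx=np.zeros(n) if tx is None else np.asarray(tx, float),
        ty=np.zeros(n) if ty is None else np.asarray(ty, float),
        **kw,
    )


@pytest.fixture
def flat_recording():
    """2000 samples of noiseless fixation at the origin."""
    return make_recording(np.zeros(2000), np.zeros(2000))
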