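import numpy as np
import pytest

from eegnetdyn.datatypes import Epoch, MultichannelRecording
from eegnetdyn.synthetic import RegimeSchedule, RegimeSegment


def pair_schedule(n_channels, duration, pairs, n_lag=0):
    """Schedule with one segment coupling the given (i, j, w, lag) pairs."""
    W = np.zeros((n_channels, n_channels))
    K = np.zeros((n_channels, n_channels), dtype=int)
    for i, j, w, lag in pairs:
        W[i, j] = W[j, i] = w
        K[i, j] = lag
        K[j, i] = -lag
    return RegimeSchedule([RegimeSegment(0.0, duration, W, K)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def white_noise_recording(rng):
    return MultichannelRecording(rng.normal(0, 10, (4, 512 * 36)), fs=512.0)


def random_symmetric(rng, n, density=1.0, signed=False, lo=0.1, hi=1.0):
    """Random symmetric zero-diagonal weight matrix."""
    W = rng.uniform(lo, hi, (n, n))
    if signed:
        W *= rng.choice([-1.0, 1.0], size=(n, n))
    if density < 1.0:
        W *= rng.random((n, n)) < density
    W = np.triu(W, 1)
    W = W + W.T
    return W


def white_epoch(rng, n_channels=4, n_samples=512, fs=512.0):
    return Epoch(rng.normal(0, 10, (n_channels, n_samples)), fs=fs, start_time=0.0)
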