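"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ecogplast.core_io import ChannelInfo, PulseEvent, Recording, SessionProtocol
from ecogplast.synthetic import NetworkConfig


def make_channels(n: int, n_bad: int = 0) -> list[ChannelInfo]:
    half = n // 2
    chans = [
        ChannelInfo(channel_id=i, grid_row=i // 8, grid_col=i % 8,
                    area="M1" if i < half else "S1", good=i >= n_bad)
        for i in range(n)
    ]
    return chans


def make_recording(n_channels=4, duration=1.0, fs=1000.0, seed=0, events=None):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_channels, int(duration * fs))).astype(np.float32)
    return Recording(data=data, fs=fs, channels=make_channels(n_channels),
                     events=events or [])


@pytest.fixture
def small_recording():
    return make_recording()


@pytest.fixture
def pulsed_recording():
    events = [PulseEvent(0.1 + k * 0.2, 0, 0.005) for k in range(20)]
    return make_recording(n_channels=4, duration=4.2, seed=1, events=events)


@pytest.fixture
def clean_config():
    """Noiseless 8-channel network for exact-construction checks."""
    W = np.zeros((8, 8))
    W[0, 4:] = [0.2, 0.4, 0.8, 0.6]
    W[1:4, 0] = 0.5
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return NetworkConfig(n_channels=8, W=W, noise_sd=0.0, pink_sd=0.0,
                         pulse_jitter_sd=0.0)


@pytest.fixture
def tiny_protocol():
    return SessionProtocol.standard(
        laser_sites=[(0, 0)], baseline_s=20.0, test_pulses=20,
        conditioning_s=20.0, n_repeats=1, final_measurement=True,
    )
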