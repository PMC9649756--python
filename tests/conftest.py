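import numpy as np
import pytest

from granuletrace import (
    GroundTruthSchedule,
    ScheduledEvent,
    TraceRenderConfig,
)

SPAN = 13


@pytest.fixture
def flat_config():
    """No bleaching, no noise: the identity-limit render configuration."""
    return TraceRenderConfig(
        c0=400.0, bleach_timescale_s=np.inf, noise_sd=0.0, frame_interval_s=10.0, n_frames=360
    )


def make_spaced_schedule(seed: int, amplitude_unit: float = 100.0, occupancy: float = 1.0):
    """Random-direction events spaced >= 3x the smoothing span, amplitudes
    quantized as amplitude_unit * max(1, Poisson(occupancy)); pre-loaded so
    shedding never clips."""
    rng = np.random.default_rng(seed)
    frames = []
    t = int(rng.integers(30, 50))
    while t < 330:
        frames.append(t)
        t += int(rng.integers(3 * SPAN, 3 * SPAN + 25))
    events = [
        ScheduledEvent(
            f * 10.0,
            "entry" if rng.random() < 0.5 else "shedding",
            amplitude_unit * max(1, int(rng.poisson(occupancy))),
        )
        for f in frames
    ]
    return GroundTruthSchedule(
        events=events, duration_s=3600.0, seed=seed, initial_content=3000.0
    )


def empty_schedule(initial_content: float = 1000.0) -> GroundTruthSchedule:
    return GroundTruthSchedule(
        events=[], duration_s=3600.0, seed=0, initial_content=initial_content
    )
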