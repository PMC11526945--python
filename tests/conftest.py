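import numpy as np
import pytest

from prospectcode import behavior as beh
from prospectcode.config import PipelineConfig
from prospectcode.geometry import TrackGeometry
from prospectcode.session import BehaviorTrace
from prospectcode.synthetic import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One synthetic session at study-default conditions, shared read-only."""
    return generate_session(SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def default_trials(default_session):
    s = default_session
    trials = beh.segment_trials(s.behavior, s.geometry)
    beh.classify_trials(trials, s.behavior, s.geometry)
    beh.split_fast_slow(trials)
    return trials


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture
def geometry():
    return TrackGeometry()


def constant_speed_trace(
    n_laps: float = 3.0, speed: float = 30.0, rate: float = 50.0,
    geometry: TrackGeometry | None = None, licks=(), rewards=(),
) -> BehaviorTrace:
    """Uniform-speed trace starting exactly at a reward-zone exit."""
    geometry = geometry or TrackGeometry()
    origin = geometry.reward_zone_ends[0]
    duration = n_laps * 360.0 / speed
    t = np.arange(0.0, duration + 1e-9, 1.0 / rate)
    pos = np.mod(origin + speed * t, 360.0)
    return BehaviorTrace(
        time=t,
        position=pos,
        speed=np.full_like(t, speed),
        licks=np.asarray(licks, dtype=float),
        rewards=np.asarray(rewards, dtype=float),
    )
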