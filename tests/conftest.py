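import numpy as np
import pytest

from oralsa.io import Event, SessionLog
from oralsa.simulate import BehaviorSimConfig, simulate_operant_session


@pytest.fixture
def tiny_log():
    """Two hand-built trials: one 2-reward bout, one single, split by >1 s gap."""
    events = []
    t = 1.0
    # trial 1: 10 licks at 7 Hz, rewards after lick 5 and lick 10 (FR5)
    for i in range(10):
        events.append(Event(round(t, 6), "lick", 1))
        if i in (4, 9):
            events.append(Event(round(t + 0.005, 6), "reward", 1))
        t += 1 / 7
    # > 1 s silence, then a single-reward trial on port 2
    t += 2.0
    for i in range(5):
        events.append(Event(round(t, 6), "lick", 2))
        if i == 4:
            events.append(Event(round(t + 0.005, 6), "reward", 2))
        t += 1 / 7
    return SessionLog(
        session_id="tiny", setup="operant",
        port_map={1: "fentanyl", 2: "quinine"},
        dose_mg_per_ml={1: 0.1, 2: 0.0},
        reward_volume_ul=10.0, schedule=5, events=events,
    )


@pytest.fixture
def operant_session():
    cfg = BehaviorSimConfig(seed=42, n_trials=80, p_terminate=0.4,
                            laser_fraction=0.5, schedule=5)
    return simulate_operant_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
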