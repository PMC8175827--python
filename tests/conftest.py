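import numpy as np
import pytest

from cuedex import (
    GameEvent,
    GameSession,
    ResponderParams,
    ScreenGeometry,
    TrajectorySample,
    simulate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def geometry():
    return ScreenGeometry()


@pytest.fixture
def default_session(rng, geometry):
    """A standard simulated 60 s session: 30 events, 15 per direction."""
    return simulate_session("S001", 1, "peanut_ball", ResponderParams(),
                            geometry, rng)


def make_manual_session(targets_rf, targets_rb, paddle_x=0.5, *,
                        task="peanut_ball", sample_rate=50.0):
    """Session with a stationary paddle and hand-chosen target positions.

    Targets alternate RF/RB so direction counts stay balanced; the paddle
    never moves, so every event whose target lies outside the capture zone is
    a miss at distance |paddle_x - target_x|.
    """
    assert len(targets_rf) == len(targets_rb)
    events = []
    i = 0
    for xa, xb in zip(targets_rf, targets_rb):
        events.append(GameEvent(event_index=i, appear_time=2.0 * i,
                                target_x=xa, direction_label="RF"))
        events.append(GameEvent(event_index=i + 1, appear_time=2.0 * (i + 1),
                                target_x=xb, direction_label="RB"))
        i += 2
    duration = 2.0 * len(events)
    n = int(duration * sample_rate) + 1
    samples = [TrajectorySample(t=k / sample_rate, paddle_x=paddle_x)
               for k in range(n)]
    return GameSession(session_id="manual", subject_id="S000", occasion=1,
                       task_name=task, geometry=ScreenGeometry(),
                       events=events, samples=samples,
                       sample_rate_hz=sample_rate)
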