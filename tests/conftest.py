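"""Shared fixtures: small simulated cohorts and trajectory sets."""

import numpy as np
import pytest

from leverkin.io_core import Event, EventLog
from leverkin.synthetic_data import make_agent, simulate_sessions
from leverkin.trial_metrics import segment_trials


def event_log_from_trials(ipi_reward_pairs, gap=3.0, animal_id="a"):
    """Build a valid event log from (ipi_s, rewarded) pairs, generous ITIs."""
    events = []
    t = 0.0
    for ipi, rewarded in ipi_reward_pairs:
        events.append(Event(t, "press"))
        events.append(Event(t + ipi, "press"))
        if rewarded:
            events.append(Event(t + ipi + 0.01, "reward", 5))
        t += ipi + gap
    return EventLog(animal_id, events).validate()


@pytest.fixture(scope="session")
def naive_log():
    log, _, _ = simulate_sessions(
        make_agent("naive"), n_sessions=5, trials_per_session=60, seed=7
    )
    return log


@pytest.fixture(scope="session")
def learner_log():
    log, _, _ = simulate_sessions(
        make_agent("learner"), n_sessions=80, trials_per_session=120, seed=3
    )
    return log


@pytest.fixture(scope="session")
def learner_trials(learner_log):
    return segment_trials(learner_log)
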