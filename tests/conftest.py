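"""Shared fixtures: hand-built sessions and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from banditmood.choice import ChoiceParams, SessionData, simulate_agent
from banditmood.task import (TrialSchedule, generate_schedule,
                             stable_config, volatile_config)


def make_schedule(winners, reward_A, reward_B, best_car=None,
                  environment="stable", rating_trials=()):
    """Build a TrialSchedule directly from explicit per-trial arrays."""
    winners = np.array(list(winners), dtype="U1")
    n = len(winners)
    flags = np.zeros(n, dtype=bool)
    for t in rating_trials:
        flags[t - 1] = True
    return TrialSchedule(
        environment=environment,
        seed=-1,
        best_car=(np.array(list(best_car), dtype="U1") if best_car is not None
                  else np.full(n, "A", dtype="U1")),
        winner=winners,
        reward_A=np.asarray(reward_A, dtype=int),
        reward_B=np.asarray(reward_B, dtype=int),
        side_of_A=np.full(n, "left", dtype="U5"),
        is_rating_trial=flags,
    )


def make_session(winners, choices, reward_A, reward_B, ratings=None,
                 **schedule_kwargs):
    """Build a SessionData from explicit winners/choices/rewards."""
    schedule = make_schedule(winners, reward_A, reward_B, **schedule_kwargs)
    choices = np.array(list(choices), dtype="U1")
    outcomes = (choices == schedule.winner).astype(int)
    chosen = np.where(choices == "A", schedule.reward_A, schedule.reward_B)
    return SessionData(schedule=schedule, choices=choices, outcomes=outcomes,
                       obtained_points=chosen * outcomes,
                       ratings=dict(ratings or {}))


@pytest.fixture(scope="session")
def stable_schedule():
    return generate_schedule(stable_config(seed=101))


@pytest.fixture(scope="session")
def volatile_schedule():
    return generate_schedule(volatile_config(seed=202))


@pytest.fixture(scope="session")
def simulated_session(volatile_schedule):
    """One additive-agent session at the volatile group-mean parameters."""
    params = ChoiceParams(model_id="additive", alpha=0.47, beta=10.0, phi=0.44)
    return simulate_agent(volatile_schedule, params, seed=7)
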