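"""Shared fixtures: the default model and the expensive closed-loop runs.

The horizon sweep, the dynamic-optimization baseline and the moving-target
run are session-scoped because several acceptance checks read different
aspects of the same simulations.
"""

from __future__ import annotations

import numpy as np
import pytest

from reachmpc import (DoProblem, NmpcConfig, SystemState, TaskSpec,
                      REFERENCE_POSTURE, default_model, forward_kinematics,
                      resimulate, run_task, solve_do)

HORIZONS = (0.2, 0.3, 0.4, 0.5, 0.8)
READ_TIME = 1.5


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def arm(model):
    return model[0]


@pytest.fixture(scope="session")
def muscles(model):
    return model[1]


@pytest.fixture(scope="session")
def rest_state():
    return SystemState(*REFERENCE_POSTURE)


@pytest.fixture(scope="session")
def initial_hand(arm):
    return forward_kinematics(np.array(REFERENCE_POSTURE), arm)


@pytest.fixture(scope="session")
def reach_target(initial_hand):
    """The 20 cm leftward fixed-task target."""
    return initial_hand + np.array([-0.20, 0.0])


@pytest.fixture(scope="session")
def horizon_records(arm, muscles):
    """Fixed-target closed-loop records to 1.5 s for each horizon."""
    records = {}
    for tph in HORIZONS:
        spec = TaskSpec(kind="fixed",
                        nmpc=NmpcConfig(horizon=tph, fixed_duration=True,
                                        max_time=READ_TIME))
        records[tph] = run_task(spec, arm, muscles)
    return records


@pytest.fixture(scope="session")
def do_solution(arm, muscles, rest_state, reach_target):
    problem = DoProblem(final_time=1.5, x0=rest_state.as_vector(),
                        target=reach_target)
    return solve_do(problem, arm, muscles)


@pytest.fixture(scope="session")
def do_record(do_solution, arm, muscles, rest_state):
    return resimulate(do_solution, rest_state, arm, muscles)


@pytest.fixture(scope="session")
def moving_record(arm, muscles):
    spec = TaskSpec(kind="moving",
                    nmpc=NmpcConfig(horizon=0.8, max_time=3.0))
    return run_task(spec, arm, muscles)
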