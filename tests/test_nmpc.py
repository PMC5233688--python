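"""Receding-horizon closed loop: shifting, stepping, full runs."""

import numpy as np
import pytest

from reachmpc import (MeshSpec, NmpcConfig, OcpProblem, SystemState,
                      forward_kinematics, nmpc_step, run_nmpc,
                      shift_warm_start, solve_ocp)
from reachmpc.params import REFERENCE_POSTURE

FLEXORS = [0, 2, 4]
EXTENSORS = [1, 3, 5]


def test_sampling_interval_is_five_percent_of_horizon():
    """The applied segment is 5 % of the horizon: 50 ms for a 1 s horizon."""
    assert NmpcConfig(horizon=1.0).delta == pytest.approx(0.05)
    assert NmpcConfig(horizon=0.8).delta == pytest.approx(0.04)


def test_config_validation():
    with pytest.raises(ValueError):
        NmpcConfig(horizon=-0.1)
    with pytest.raises(ValueError):
        NmpcConfig(horizon=0.5, application_fraction=0.0)
    with pytest.raises(ValueError):
        NmpcConfig(horizon=0.5, stop_threshold=0.0)


class TestShiftWarmStart:
    @pytest.fixture(scope="class")
    def solution(self, arm, muscles, rest_state, reach_target):
        spec = OcpProblem(0.0, 0.3, rest_state.as_vector(), 20.0, 1.0,
                          reach_target, mesh=MeshSpec(6, 3))
        return solve_ocp(spec, arm, muscles)

    def test_zero_shift_is_identity(self, solution):
        shifted = shift_warm_start(solution, 0.0)
        assert np.allclose(shifted.states, solution.states, atol=1e-10)
        assert np.allclose(shifted.controls, solution.controls, atol=1e-10)

    def test_full_shift_holds_terminal_values(self, solution):
        shifted = shift_warm_start(solution, solution.horizon)
        assert np.allclose(shifted.states,
                           np.tile(solution.states[-1], (len(shifted.times), 1)),
                           atol=1e-8)

    def test_shift_evaluates_previous_interpolant(self, solution):
        """The shifted guess at its node times equals the previous solution
        at the shifted times (exact interpolant identity)."""
        delta = 0.015
        shifted = shift_warm_start(solution, delta)
        probe = solution.times[1:-2]
        assert np.allclose(shifted.interp_x(probe)[:, 0:2],
                           solution.interp_x(probe + delta)[:, 0:2],
                           atol=1e-9)


class TestNmpcStep:
    def test_at_target_is_a_no_op(self, arm, muscles, rest_state):
        target = forward_kinematics(rest_state.joint_angles, arm)
        cfg = NmpcConfig(horizon=0.2, target=target)
        traj, x_new, sol = nmpc_step(rest_state, None, cfg, 0.0,
                                     arm, muscles)
        # the solver leaves a little co-contraction; the hand stays put
        assert np.abs(sol.controls).max() < 0.05
        from reachmpc import forward_kinematics as fk
        assert np.linalg.norm(fk(x_new[0:2], arm) - target) < 1e-3

    def test_first_step_recruits_flexors(self, arm, muscles, rest_state,
                                         reach_target):
        """Toward a leftward target, the flexor group dominates the applied
        excitation from the very first horizon."""
        cfg = NmpcConfig(horizon=0.4, target=reach_target)
        _, _, sol = nmpc_step(rest_state, None, cfg, 0.0, arm, muscles)
        ts = np.linspace(0.0, cfg.delta, 21)
        u = sol.interp_u(ts)
        assert u[:, FLEXORS].sum() > u[:, EXTENSORS].sum()


class TestRunNmpc:
    def test_starting_on_target_terminates_immediately(
            self, arm, muscles, rest_state):
        target = forward_kinematics(rest_state.joint_angles, arm)
        cfg = NmpcConfig(horizon=0.3, target=target)
        rec = run_nmpc(rest_state, cfg, arm, muscles)
        assert rec.t.size == 1
        assert rec.diagnostics == []

    def test_short_closed_loop_record_invariants(self, arm, muscles,
                                                 rest_state, reach_target):
        cfg = NmpcConfig(horizon=0.2, target=reach_target,
                         fixed_duration=True, max_time=0.15)
        rec = run_nmpc(rest_state, cfg, arm, muscles)
        assert np.all(np.diff(rec.t) > 0)
        assert np.all(rec.states[:, 4:10] >= -1e-9)
        assert np.all(rec.states[:, 4:10] <= 1 + 1e-9)
        assert np.all(rec.excitations >= 0) and np.all(rec.excitations <= 1)
        # stored hand positions are the forward kinematics of the angles
        assert np.abs(rec.hand
                      - forward_kinematics(rec.states[:, 0:2], arm)).max() \
            < 1e-12
        # the loop made progress toward the target
        d0 = np.linalg.norm(rec.hand[0] - reach_target)
        dT = np.linalg.norm(rec.hand[-1] - reach_target)
        assert dT < d0

    def test_closed_loop_is_deterministic(self, arm, muscles, rest_state,
                                          reach_target):
        cfg = NmpcConfig(horizon=0.2, target=reach_target,
                         fixed_duration=True, max_time=0.1)
        r1 = run_nmpc(rest_state, cfg, arm, muscles)
        r2 = run_nmpc(rest_state, cfg, arm, muscles)
        assert np.abs(r1.states - r2.states).max() < 1e-10
        assert np.abs(r1.excitations - r2.excitations).max() < 1e-10
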