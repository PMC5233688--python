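"""Direct-collocation transcription and single-horizon solves."""

import numpy as np
import pytest

from reachmpc import (MeshSpec, OcpProblem, REFERENCE_POSTURE, SystemState,
                      effort_cost, forward_kinematics, running_cost,
                      solve_ocp, transcribe)
from reachmpc.collocation import radau_scheme
from reachmpc.dynamics import integrate_plant


class TestRadauScheme:
    @pytest.mark.parametrize("d", [2, 3, 5])
    def test_differentiation_exact_on_polynomials(self, d):
        c, D, w = radau_scheme(d)
        nodes = np.concatenate(([0.0], c))
        for p in range(1, d + 1):
            assert np.allclose(D @ nodes ** p, p * c ** (p - 1), atol=1e-10)

    @pytest.mark.parametrize("d", [2, 3, 5])
    def test_quadrature_order(self, d):
        c, D, w = radau_scheme(d)
        for p in range(2 * d - 1):
            assert w @ c ** p == pytest.approx(1.0 / (p + 1), abs=1e-12)

    def test_includes_right_endpoint(self):
        c, _, _ = radau_scheme(3)
        assert c[-1] == 1.0

    def test_mesh_refinement_doubles_intervals(self):
        from reachmpc import MeshSpec

        assert MeshSpec(10, 3).refined() == MeshSpec(20, 3)


class TestCosts:
    def test_effort_examples(self):
        assert effort_cost(np.ones(6)) == 6.0
        assert effort_cost(np.zeros(6)) == 0.0
        assert effort_cost(np.array([0.5, 0, 0, 0, 0, 0])) == 0.25

    def test_running_cost(self, arm, rest_state):
        x = rest_state.as_vector()
        zeta = forward_kinematics(x[0:2], arm)
        spec = OcpProblem(0.0, 0.4, x, tracking_weight=20.0,
                          effort_weight=1.0, target=zeta)
        assert running_cost(x, np.zeros(6), spec, 0.0, arm) == \
            pytest.approx(0.0, abs=1e-15)
        spec_off = OcpProblem(0.0, 0.4, x, 20.0, 1.0,
                              target=zeta + np.array([0.1, 0.0]))
        assert running_cost(x, np.zeros(6), spec_off, 0.0, arm) == \
            pytest.approx(0.2, rel=1e-12)
        spec_p0 = OcpProblem(0.0, 0.4, x, 0.0, 3.0, target=zeta)
        u = np.full(6, 0.5)
        assert running_cost(x, u, spec_p0, 0.0, arm) == \
            pytest.approx(3.0 * effort_cost(u), rel=1e-12)

    def test_degenerate_weights_rejected(self, rest_state):
        with pytest.raises(ValueError):
            OcpProblem(0.0, 0.4, rest_state.as_vector(),
                       tracking_weight=0.0, effort_weight=0.0)


def test_decision_vector_layout(arm, muscles, rest_state):
    """K=1, d=3: 3 nodes x (10 states + 6 controls) variables, 30 defects."""
    spec = OcpProblem(0.0, 0.1, rest_state.as_vector(), target=np.zeros(2),
                      mesh=MeshSpec(1, 3))
    nlp = transcribe(spec, arm, muscles)
    assert nlp.n == 3 * 16
    assert nlp.m == 30
    assert len(nlp.bounds()) == nlp.n


def test_defect_convergence_order(arm, muscles):
    """Defect residuals of an integrated trajectory vanish at order >= d.

    The trajectory starts beyond the initial activation transient and the
    control is smooth, so the exact solution is smooth where sampled.
    """
    def u_of_t(t):
        return 0.15 + 0.1 * np.sin(2 * np.pi * 1.5 * t + np.arange(6))

    x_start = np.concatenate((REFERENCE_POSTURE, [0.0, 0.0], u_of_t(0.0)))
    pre = integrate_plant(x_start, u_of_t, 0.3, arm, muscles,
                          rtol=1e-11, atol=1e-12)
    x1 = pre.state(0.3)
    traj = integrate_plant(x1, u_of_t, 0.4, arm, muscles, t0=0.3,
                           rtol=1e-11, atol=1e-12)
    residuals = []
    for K in (4, 8, 16):
        spec = OcpProblem(0.3, 0.4, x1, target=np.zeros(2),
                          mesh=MeshSpec(K, 3))
        nlp = transcribe(spec, arm, muscles)
        X = traj.sample(nlp.t_nodes)
        U = np.array([u_of_t(t) for t in nlp.t_nodes])
        residuals.append(np.abs(
            nlp.constraints(nlp.pack(X, U))[:nlp.n_defect]).max())
    orders = np.log2(np.array(residuals[:-1]) / np.array(residuals[1:]))
    assert orders.min() >= 3.0


class TestSolve:
    def test_at_target_solution_is_idle(self, arm, muscles, rest_state):
        """Starting on target at rest, doing nothing is optimal."""
        x = rest_state.as_vector()
        zeta = forward_kinematics(x[0:2], arm)
        spec = OcpProblem(0.0, 0.2, x, 20.0, 1.0, zeta, mesh=MeshSpec(5, 3))
        sol = solve_ocp(spec, arm, muscles)
        assert sol.usable
        assert sol.objective < 1e-3
        assert np.abs(sol.controls).max() < 0.05

    def test_solution_respects_bounds_and_feasibility(
            self, arm, muscles, rest_state, reach_target):
        spec = OcpProblem(0.0, 0.3, rest_state.as_vector(), 20.0, 1.0,
                          reach_target, mesh=MeshSpec(8, 3))
        sol = solve_ocp(spec, arm, muscles)
        assert sol.usable
        assert sol.defect_max <= 1e-5
        assert np.all(sol.controls >= -1e-8)
        assert np.all(sol.controls <= 1 + 1e-8)
        assert np.all(sol.states[:, 4:10] >= -1e-8)
        assert np.all(sol.states[:, 4:10] <= 1 + 1e-8)

    def test_deterministic_resolve(self, arm, muscles, rest_state,
                                   reach_target):
        """Identical inputs and settings give identical solutions."""
        spec = OcpProblem(0.0, 0.2, rest_state.as_vector(), 20.0, 1.0,
                          reach_target, mesh=MeshSpec(5, 3))
        s1 = solve_ocp(spec, arm, muscles)
        s2 = solve_ocp(OcpProblem(0.0, 0.2, rest_state.as_vector(), 20.0,
                                  1.0, reach_target, mesh=MeshSpec(5, 3)),
                       arm, muscles)
        assert s1.objective == s2.objective
        assert np.array_equal(s1.states, s2.states)
        assert np.array_equal(s1.controls, s2.controls)

    def test_warm_start_from_own_solution_is_stable(
            self, arm, muscles, rest_state, reach_target):
        spec = OcpProblem(0.0, 0.2, rest_state.as_vector(), 20.0, 1.0,
                          reach_target, mesh=MeshSpec(5, 3))
        s1 = solve_ocp(spec, arm, muscles)
        s2 = solve_ocp(spec, arm, muscles, initial_guess=s1)
        assert s2.usable
        # re-polishing from the incumbent never degrades the objective
        assert s2.objective <= s1.objective * 1.01 + 1e-9

    def test_dropping_effort_term_cannot_cost_more(
            self, arm, muscles, rest_state, reach_target):
        """With q=0 the optimum is no larger than the q=1 tracking part."""
        base = OcpProblem(0.0, 0.25, rest_state.as_vector(), 20.0, 1.0,
                          reach_target, mesh=MeshSpec(6, 3))
        with_effort = solve_ocp(base, arm, muscles)
        no_effort = solve_ocp(
            OcpProblem(0.0, 0.25, rest_state.as_vector(), 20.0, 0.0,
                       reach_target, mesh=MeshSpec(6, 3)), arm, muscles)
        assert no_effort.usable
        assert no_effort.objective <= with_effort.objective + 1e-6


def test_problem_yaml_round_trip(tmp_path, rest_state, reach_target):
    spec = OcpProblem(0.1, 0.4, rest_state.as_vector(), 20.0, 2.0,
                      reach_target, mesh=MeshSpec(7, 3),
                      terminal_state=np.zeros(10),
                      terminal_mask=np.array([True] * 4 + [False] * 6))
    path = tmp_path / "ocp.yaml"
    spec.to_yaml(path)
    back = OcpProblem.from_yaml(path)
    assert back.horizon == spec.horizon
    assert np.allclose(back.x0, spec.x0)
    assert np.allclose(back.target, reach_target)
    assert back.mesh.intervals == 7
    assert np.array_equal(back.terminal_mask, spec.terminal_mask)
    ref = OcpProblem(0.0, 0.4, rest_state.as_vector(),
                     target=lambda t: np.zeros(2))
    with pytest.raises(ValueError):
        ref.to_yaml(tmp_path / "bad.yaml")


def test_terminal_cost_hook(arm, muscles, rest_state):
    """The optional end-point cost enters the objective and its gradient."""
    x = rest_state.as_vector()
    zeta = forward_kinematics(x[0:2], arm)
    pull = np.radians(50.0)    # quadratic pull on the terminal shoulder angle

    def psi(xf):
        return 5.0 * (xf[0] - pull) ** 2

    spec = OcpProblem(0.0, 0.2, x, 20.0, 1.0, zeta, terminal_cost=psi,
                      mesh=MeshSpec(4, 3))
    nlp = transcribe(spec, arm, muscles)
    z = nlp.initial_guess()
    base = OcpProblem(0.0, 0.2, x, 20.0, 1.0, zeta, mesh=MeshSpec(4, 3))
    nlp0 = transcribe(base, arm, muscles)
    assert nlp.objective(z) == pytest.approx(
        nlp0.objective(z) + psi(nlp.split(z)[0][-1]), rel=1e-12)
    # gradient of the hook (complex-step assembled) matches finite differences
    j = (nlp.N - 1) * 10
    dz = np.zeros_like(z)
    dz[j] = 1e-6
    fd = (nlp.objective(z + dz) - nlp.objective(z - dz)) / 2e-6
    assert nlp.gradient(z)[j] == pytest.approx(fd, rel=1e-5)


def test_collocation_matches_integration_for_smooth_solution(
        arm, muscles, rest_state):
    """Simulating under the solution's own control interpolant reproduces
    the collocation trajectory when the optimal control is smooth (high
    effort weight keeps the controls off their bounds and ringing-free)."""
    x0 = rest_state.as_vector()
    x0[4:10] = 0.05
    zeta0 = forward_kinematics(x0[0:2], arm)
    spec = OcpProblem(0.0, 0.4, x0, 20.0, 100.0,
                      zeta0 + np.array([-0.04, 0.0]), mesh=MeshSpec(20, 3))
    sol = solve_ocp(spec, arm, muscles, max_iter=400)
    assert sol.usable
    traj = integrate_plant(x0, sol.interp_u, 0.4, arm, muscles,
                           rtol=1e-10, atol=1e-10)
    diff = np.linalg.norm(traj.state(0.4) - sol.states[-1])
    assert diff <= 1e-3
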