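"""Muscle geometry, Hill curves, forces and activation dynamics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from reachmpc import (MuscleSet, REFERENCE_POSTURE, muscle_force,
                      activation_dynamics, active_force_length,
                      force_velocity, passive_force_length, muscle_geometry,
                      ModelDegeneracyError)
from reachmpc.dynamics import integrate_plant
from reachmpc.params import SystemState

FLEXORS = [0, 2, 4]
EXTENSORS = [1, 3, 5]


def posture_grid(n=20):
    t1 = np.radians(np.linspace(15, 125, n))
    t2 = np.radians(np.linspace(15, 125, n))
    T1, T2 = np.meshgrid(t1, t2, indexing="ij")
    return np.stack([T1, T2], axis=-1)


def test_mono_articular_muscles_have_zero_cross_moment_arms(arm, muscles):
    _, R = muscle_geometry(posture_grid(), arm, muscles)
    # shoulder muscles 1, 2: no elbow moment arm; elbow muscles 3, 4: no
    # shoulder moment arm
    assert np.allclose(R[..., 1, [0, 1]], 0.0, atol=1e-15)
    assert np.allclose(R[..., 0, [2, 3]], 0.0, atol=1e-15)


def test_biarticular_muscles_span_both_joints(arm, muscles):
    _, R = muscle_geometry(np.array(REFERENCE_POSTURE), arm, muscles)
    assert np.all(np.abs(R[:, [4, 5]]) > 1e-3)


def test_moment_arms_match_central_differences(arm, muscles):
    """Analytic moment arms agree with -dL/dq to 1e-8 over a posture grid."""
    Q = posture_grid()
    _, R = muscle_geometry(Q, arm, muscles)
    eps = 1e-6
    for j in range(2):
        dq = np.zeros(2)
        dq[j] = eps
        Lp, _ = muscle_geometry(Q + dq, arm, muscles)
        Lm, _ = muscle_geometry(Q - dq, arm, muscles)
        numeric = -(Lp - Lm) / (2 * eps)
        assert np.abs(numeric - R[..., j, :]).max() < 1e-8


def test_flexor_extensor_moment_arm_signs(arm, muscles):
    """Antagonist pairs pull opposite ways at every grid posture."""
    _, R = muscle_geometry(posture_grid(), arm, muscles)
    assert np.all(R[..., 0, 0] > 0)      # shoulder flexor
    assert np.all(R[..., 0, 1] < 0)      # shoulder extensor
    assert np.all(R[..., 1, 2] > 0)      # elbow flexor
    assert np.all(R[..., 1, 3] < 0)      # elbow extensor
    assert np.all(R[..., 0, 4] > 0)      # bi-articular flexor, both joints
    assert np.all(R[..., 1, 4] > 0)
    assert np.all(R[..., 0, 5] < 0)      # bi-articular extensor
    assert np.all(R[..., 1, 5] < 0)


class TestHillCurves:
    def test_anchor_values(self):
        assert active_force_length(1.0) == 1.0
        assert force_velocity(0.0) == 1.0
        assert passive_force_length(1.0) == pytest.approx(0.0, abs=1e-12)
        assert passive_force_length(1.6) == pytest.approx(1.0, abs=2e-3)
        assert abs(passive_force_length(0.8)) < 1e-3

    def test_force_velocity_shape(self):
        v = np.linspace(-2.0, 3.0, 800)
        fv = force_velocity(v)
        assert np.all(np.diff(fv) >= -1e-12)          # monotone
        assert abs(force_velocity(-1.0)) < 1e-3       # ~0 at max shortening
        assert np.all(fv <= 1.4 + 1e-12)              # eccentric plateau

    def test_isometric_slope(self):
        eps = 1e-7
        slope = (force_velocity(eps) - force_velocity(-eps)) / (2 * eps)
        assert slope == pytest.approx(1.0 + 1.0 / 0.25, rel=1e-4)


class TestMuscleForce:
    def test_passive_only_zero_at_optimal_length(self, arm, muscles):
        q = np.array(REFERENCE_POSTURE)         # fibres calibrated here
        for m in range(6):
            F = muscle_force(0.0, m, q, np.zeros(2), arm, muscles)
            assert F == pytest.approx(0.0, abs=1e-9)

    def test_full_activation_isometric(self, arm, muscles):
        """At optimal length and zero velocity: F = F0max cos(alpha)."""
        q = np.array(REFERENCE_POSTURE)
        F = muscle_force(1.0, 0, q, np.zeros(2), arm, muscles)
        assert F == pytest.approx(2525.0 * math.cos(math.radians(21.6)),
                                  rel=1e-9)
        assert F == pytest.approx(2347.7, abs=0.1)

    def test_degenerate_fiber_raises(self, arm, muscles):
        long_slack = replace(muscles.muscles[0], tendon_slack_length=0.5,
                             optimal_fiber_length=0.1)
        broken = MuscleSet([long_slack] + list(muscles.muscles[1:]))
        with pytest.raises(ModelDegeneracyError):
            muscle_force(0.5, 0, np.array(REFERENCE_POSTURE), np.zeros(2),
                         arm, broken)

    def test_activation_bounds_validated(self, arm, muscles):
        with pytest.raises(ValueError):
            muscle_force(1.5, 0, np.array(REFERENCE_POSTURE), np.zeros(2),
                         arm, muscles)


class TestActivationDynamics:
    def test_fixed_point(self, muscles):
        assert np.allclose(activation_dynamics(
            np.full(6, 0.3), np.full(6, 0.3), muscles), 0.0)

    def test_full_step_rate(self, muscles):
        rate = activation_dynamics(np.zeros(6), np.ones(6), muscles)
        assert rate == pytest.approx(np.full(6, 100.0), rel=1e-6)

    def test_first_order_step_response(self, arm, muscles):
        """a(tau_act) = 1 - 1/e for a 0 -> 1 excitation step."""
        x0 = SystemState(*REFERENCE_POSTURE).as_vector()
        traj = integrate_plant(x0, np.ones(6), 0.010, arm, muscles,
                               rtol=1e-10, atol=1e-12)
        a = traj.state(0.010)[4:10]
        assert a == pytest.approx(np.full(6, 1 - math.exp(-1)), abs=1e-3)

    def test_unit_box_invariance(self, arm, muscles):
        """Activations stay in [0, 1] under bang-bang excitation."""
        rng = np.random.default_rng(3)
        x0 = SystemState(*REFERENCE_POSTURE,
                         activations=rng.uniform(0, 1, 6)).as_vector()
        switch = rng.uniform(0.05, 0.45, 6)
        levels = rng.integers(0, 2, (6, 2)).astype(float)

        def u_of_t(t):
            return np.where(t < switch, levels[:, 0], levels[:, 1])

        traj = integrate_plant(x0, u_of_t, 0.5, arm, muscles)
        for t in np.linspace(0, 0.5, 26):
            a = traj.state(t)[4:10]
            assert np.all(a >= -1e-9) and np.all(a <= 1 + 1e-9)
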