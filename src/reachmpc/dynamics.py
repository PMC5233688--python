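"""Plant dynamics f(x, u) of the muscle-driven planar arm, and its simulation.

State (10-vector): theta1, theta2, theta1_dot, theta2_dot, a1..a6.
Control (6-vector): neural excitations u1..u6.

Joint accelerations solve

    M(q) q̈ + C(q, q̇) q̇ + D q̇ = R(q) F(a, q, q̇)

with M the two-link mass matrix, C the Coriolis/centrifugal matrix, D
(optional) viscous joint damping, R the 2x6 moment-arm matrix and F the six
Hill-muscle tendon forces.  There is no gravity term: the task plane is
horizontal.  The activation rows follow the first-order
excitation-to-activation dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .arm import coriolis_matrix, mass_matrix, solve_2x2
from .muscles import activation_rate, musculotendon_geometry, tendon_forces
from .params import ArmParameters, MuscleSet, SystemState, check_excitations

_CS_STEP = 1e-30  # complex-step size; derivatives exact to machine precision


def dynamics_vec(X, U, arm: ArmParameters, muscles: MuscleSet,
                 include_muscles: bool = True):
    """Vectorized state derivative; X is (..., 10), U is (..., 6).

    Complex-safe.  ``include_muscles=False`` turns all muscle forces off
    (ballistic limb), used by the energy-conservation checks.
    """
    X = np.asarray(X)
    U = np.asarray(U)
    t1, t2 = X[..., 0], X[..., 1]
    qd = X[..., 2:4]
    a = X[..., 4:10]
    q = X[..., 0:2]

    if include_muscles:
        lengths, R = musculotendon_geometry(t1, t2, arm, muscles)
        # musculotendon lengthening rate: dL/dt = -R^T q̇
        vel = -(R[..., 0, :] * qd[..., 0:1] + R[..., 1, :] * qd[..., 1:2])
        F = tendon_forces(a, lengths, vel, muscles)
        tau = np.einsum("...jm,...m->...j", R, F)
    else:
        tau = np.zeros_like(qd)

    M = mass_matrix(q, arm)
    C = coriolis_matrix(q, qd, arm)
    rhs = tau - np.einsum("...ij,...j->...i", C, qd) - arm.joint_damping * qd
    qdd = solve_2x2(M, rhs)
    adot = activation_rate(a, U, muscles) if include_muscles \
        else np.zeros_like(a)
    return np.concatenate((qd, qdd, adot), axis=-1)


def dynamics(x: SystemState | np.ndarray, u, arm: ArmParameters,
             muscles: MuscleSet) -> np.ndarray:
    """State derivative for a single validated state/excitation pair."""
    if isinstance(x, SystemState):
        x = x.as_vector()
    u = check_excitations(u)
    return dynamics_vec(np.asarray(x, dtype=float), u, arm, muscles)


def dynamics_jacobians(X, U, arm: ArmParameters, muscles: MuscleSet):
    """Exact Jacobians A = df/dx (..., 10, 10) and B = df/du (..., 10, 6).

    Computed column-by-column with complex-step differentiation of the
    (complex-transparent) dynamics; accurate to machine precision away from
    the model's isolated switching surfaces.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    A = np.empty(X.shape[:-1] + (10, 10))
    B = np.empty(X.shape[:-1] + (10, 6))
    Xc = X.astype(complex)
    Uc = U.astype(complex)
    for j in range(10):
        Xc[..., j] += 1j * _CS_STEP
        A[..., j] = dynamics_vec(Xc, U, arm, muscles).imag / _CS_STEP
        Xc[..., j] = X[..., j]
    for j in range(6):
        Uc[..., j] += 1j * _CS_STEP
        B[..., j] = dynamics_vec(X, Uc, arm, muscles).imag / _CS_STEP
        Uc[..., j] = U[..., j]
    return A, B


class IntegrationError(RuntimeError):
    """Plant integration failure, carrying the time at which it occurred."""

    def __init__(self, message: str, t_failure: float):
        super().__init__(f"{message} (t = {t_failure:.6f} s)")
        self.t_failure = t_failure


@dataclass
class PlantTrajectory:
    """Dense-output result of a plant simulation over [t0, t0 + duration]."""

    t0: float
    duration: float
    _sol: object
    control: Callable[[float], np.ndarray]

    @property
    def t_final(self) -> float:
        return self.t0 + self.duration

    def state(self, t) -> np.ndarray:
        """Interpolated state; activations clipped to [0, 1] (they stay inside
        up to integration tolerance)."""
        x = np.asarray(self._sol(t))  # (10,) or (10, nt)
        x[4:10] = np.clip(x[4:10], 0.0, 1.0)
        return x

    def terminal_state(self) -> SystemState:
        return SystemState.from_vector(self.state(self.t_final))

    def sample(self, times: np.ndarray) -> np.ndarray:
        """States at an array of times, shape (len(times), 10)."""
        out = np.asarray(self._sol(np.asarray(times))).T
        out[:, 4:10] = np.clip(out[:, 4:10], 0.0, 1.0)
        return out


def integrate_plant(x0: SystemState | np.ndarray,
                    control,
                    duration: float,
                    arm: ArmParameters,
                    muscles: MuscleSet,
                    t0: float = 0.0,
                    rtol: float = 1e-8,
                    atol: float = 1e-8,
                    include_muscles: bool = True) -> PlantTrajectory:
    """Simulate the plant under a control signal with adaptive Runge-Kutta.

    ``control`` may be a constant 6-vector or a callable ``t -> u(t)``; the
    declared interpolation of the caller is honoured by evaluating the
    callable at the integrator's internal times.  ``duration`` may be zero,
    in which case the trajectory is constant at ``x0``.
    """
    if isinstance(x0, SystemState):
        x0 = x0.as_vector()
    x0 = np.asarray(x0, dtype=float)
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if callable(control):
        u_of_t = control
    else:
        u_const = check_excitations(control)
        u_of_t = lambda t: u_const  # noqa: E731

    if duration == 0.0:
        sol = lambda t: np.broadcast_to(  # noqa: E731
            x0[:, None] if np.ndim(t) else x0,
            (10, np.size(t)) if np.ndim(t) else (10,)).copy()
        return PlantTrajectory(t0, 0.0, sol, u_of_t)

    def rhs(t, x):
        u = np.clip(np.asarray(u_of_t(t), dtype=float), 0.0, 1.0)
        return dynamics_vec(x, u, arm, muscles, include_muscles=include_muscles)

    res = solve_ivp(rhs, (t0, t0 + duration), x0, method="RK45",
                    rtol=rtol, atol=atol, dense_output=True)
    if not res.success:
        raise IntegrationError(res.message, float(res.t[-1]))
    return PlantTrajectory(t0, duration, res.sol, u_of_t)
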