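"""Skeletal kinematics and rigid-body dynamics terms of the planar arm.

Frame convention: shoulder at the origin, x to the subject's right, y
anterior (the plane is horizontal, at shoulder height, so gravity plays no
role).  ``theta1`` is the shoulder angle measured from +x to the upper arm;
``theta2`` is the elbow flexion angle of the forearm relative to the upper
arm, so the forearm points along ``theta1 + theta2``.  The hand is the distal
end of the forearm.

All functions accept scalars or arrays (vectorized over leading axes) and are
transparent to complex input, which the optimal-control layer exploits for
complex-step differentiation.
"""

from __future__ import annotations

import numpy as np

from .params import ArmParameters


def _check_finite(*vals) -> None:
    for v in vals:
        arr = np.asarray(v)
        if not np.all(np.isfinite(arr.real)) or (
                np.iscomplexobj(arr) and not np.all(np.isfinite(arr.imag))):
            raise ValueError("non-finite input")


def forward_kinematics(q, params: ArmParameters):
    """Hand position (m) in the shoulder frame for joint angles ``q``.

    ``q`` is ``(theta1, theta2)`` or an array with the last axis of length 2;
    the result has the same leading shape with a trailing axis of length 2.
    """
    q = np.asarray(q)
    _check_finite(q)
    t1 = q[..., 0]
    t12 = q[..., 0] + q[..., 1]
    L1, L2 = params.upper_arm_length, params.forearm_length
    return np.stack((L1 * np.cos(t1) + L2 * np.cos(t12),
                     L1 * np.sin(t1) + L2 * np.sin(t12)), axis=-1)


def hand_jacobian(q, params: ArmParameters):
    """Jacobian d(hand)/d(theta1, theta2), shape (..., 2, 2)."""
    q = np.asarray(q)
    t1 = q[..., 0]
    t12 = q[..., 0] + q[..., 1]
    L1, L2 = params.upper_arm_length, params.forearm_length
    s1, c1 = np.sin(t1), np.cos(t1)
    s12, c12 = np.sin(t12), np.cos(t12)
    row0 = np.stack((-L1 * s1 - L2 * s12, -L2 * s12), axis=-1)
    row1 = np.stack((L1 * c1 + L2 * c12, L2 * c12), axis=-1)
    return np.stack((row0, row1), axis=-2)


class UnreachableTargetError(ValueError):
    """Raised when a hand target lies outside the reachable annulus."""


def inverse_kinematics(target, params: ArmParameters,
                       elbow_positive: bool = True) -> np.ndarray:
    """Joint angles reproducing a hand ``target``; two-link closed form.

    ``elbow_positive`` selects the elbow-flexed-positive branch (theta2 >= 0,
    the default) or its mirror.  Raises :class:`UnreachableTargetError` for
    targets outside the annulus ``|L1 - L2| <= ||target|| <= L1 + L2``.
    """
    target = np.asarray(target, dtype=float)
    _check_finite(target)
    L1, L2 = params.upper_arm_length, params.forearm_length
    r = float(np.hypot(target[0], target[1]))
    lo, hi = abs(L1 - L2), L1 + L2
    if not (lo - 1e-12 <= r <= hi + 1e-12):
        raise UnreachableTargetError(
            f"target at distance {r:.4f} m outside reachable annulus "
            f"[{lo:.4f}, {hi:.4f}] m")
    c2 = (r * r - L1 * L1 - L2 * L2) / (2 * L1 * L2)
    c2 = min(1.0, max(-1.0, c2))
    t2 = np.arccos(c2)
    if not elbow_positive:
        t2 = -t2
    t1 = np.arctan2(target[1], target[0]) - np.arctan2(
        L2 * np.sin(t2), L1 + L2 * np.cos(t2))
    return np.array([t1, t2])


def reachable(target, params: ArmParameters, margin: float = 0.0) -> bool:
    """Whether ``target`` lies within the reachable annulus (with margin)."""
    r = float(np.hypot(*np.asarray(target, dtype=float)))
    L1, L2 = params.upper_arm_length, params.forearm_length
    return abs(L1 - L2) + margin <= r <= L1 + L2 - margin


def mass_matrix(q, params: ArmParameters):
    """Joint-space mass matrix M(q), shape (..., 2, 2).

    Standard two-link form; symmetric positive definite for any physical
    parameter set.
    """
    q = np.asarray(q)
    c2 = np.cos(q[..., 1])
    p = params
    m2, L1 = p.forearm_mass, p.upper_arm_length
    lc1, lc2 = p.upper_arm_com, p.forearm_com
    I1, I2 = p.upper_arm_inertia, p.forearm_inertia
    a = I1 + I2 + p.upper_arm_mass * lc1 ** 2 + m2 * (L1 ** 2 + lc2 ** 2)
    b = m2 * L1 * lc2
    m11 = a + 2 * b * c2
    m12 = I2 + m2 * lc2 ** 2 + b * c2
    m22 = I2 + m2 * lc2 ** 2 + np.zeros_like(c2)
    row0 = np.stack((m11, m12), axis=-1)
    row1 = np.stack((m12, m22), axis=-1)
    return np.stack((row0, row1), axis=-2)


def coriolis_matrix(q, qdot, params: ArmParameters):
    """Coriolis/centrifugal matrix C(q, q̇) with tau = C q̇, shape (..., 2, 2).

    Built with the Christoffel convention, so that dM/dt - 2C is
    skew-symmetric.
    """
    q = np.asarray(q)
    qdot = np.asarray(qdot)
    h = params.forearm_mass * params.upper_arm_length * params.forearm_com \
        * np.sin(q[..., 1])
    d1, d2 = qdot[..., 0], qdot[..., 1]
    zero = np.zeros_like(h)
    row0 = np.stack((-h * d2, -h * (d1 + d2)), axis=-1)
    row1 = np.stack((h * d1, zero), axis=-1)
    return np.stack((row0, row1), axis=-2)


def solve_2x2(M, rhs):
    """Solve M x = rhs for stacked 2x2 systems (complex-safe closed form)."""
    a, b = M[..., 0, 0], M[..., 0, 1]
    c, d = M[..., 1, 0], M[..., 1, 1]
    det = a * d - b * c
    if np.any(np.abs(det) < 1e-14):
        raise np.linalg.LinAlgError("singular mass matrix")
    x0 = (d * rhs[..., 0] - b * rhs[..., 1]) / det
    x1 = (-c * rhs[..., 0] + a * rhs[..., 1]) / det
    return np.stack((x0, x1), axis=-1)


def kinetic_energy(q, qdot, params: ArmParameters):
    """Total kinetic energy (J); the mechanical energy in the horizontal plane."""
    M = mass_matrix(q, params)
    qd = np.asarray(qdot)
    return 0.5 * np.einsum("...i,...ij,...j->...", qd, M, qd)
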