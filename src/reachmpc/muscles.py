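"""Muscle path geometry, Hill-type contraction model and activation dynamics.

The contraction model is a rigid-tendon Hill muscle: the musculotendon path
is a straight line from origin to insertion through the current segment
poses; fibre length is the path length minus the tendon slack length, scaled
by the (constant) pennation cosine.  Because the tendon is rigid there are no
fibre-length states — consistent with a 10-dimensional plant state that
carries only joint kinematics and the six activations.

Force components (all dimensionless, scaled by ``F0max * cos(alpha_p)``):

- active force–length: Gaussian, ``f_L(l) = exp(-((l - 1)/0.45)^2)``
- force–velocity: a single globally analytic Hill-like curve — zero at
  full-speed shortening (10 optimal fibre lengths/s), exactly 1 at
  isometric with slope 1 + 1/0.25, saturating at an eccentric plateau of
  1.4.  Using one analytic expression instead of a piecewise
  concentric/eccentric switch keeps the vector field smooth, which direct
  collocation needs to converge at design order.
- passive force–length: exponential in a softplus-smoothed stretch, shifted
  to be exactly zero at optimal length and reaching 1 at 1.6 optimal
  lengths; below optimal length it is negligible (|f_PE| < 1e-3).

Excitation-to-activation coupling is first order with a 10 ms activation and
40 ms deactivation time constant; the constant switch at u = a is blended
over a narrow sigmoid so the dynamics stay differentiable.

All functions are vectorized and transparent to complex inputs (used for
complex-step differentiation); branch decisions are taken on real parts.
"""

from __future__ import annotations

import numpy as np

from .params import ArmParameters, MuscleSet, GROUND, UPPER_ARM

FL_WIDTH = 0.45          # Gaussian width of the active force-length curve
FV_CURVATURE = 0.25      # Hill shape parameter a_f (sets isometric slope)
FV_ECC_PLATEAU = 1.4     # eccentric force plateau
VMAX_SCALE = 10.0        # max shortening velocity, optimal fibre lengths / s
PE_SHAPE = 10.0          # passive curve exponent
_FV_SLOPE0 = 1.0 + 1.0 / FV_CURVATURE    # d f_V/d v at v = 0
_FV_GAIN = 2.0 * _FV_SLOPE0 / (FV_ECC_PLATEAU - 1.0)
# softplus width chosen so f_V(-1) ~ 0 (exp(+gain*w*log 2) = plateau/(plateau-1))
_FV_SOFT = np.log(FV_ECC_PLATEAU / (FV_ECC_PLATEAU - 1.0)) / (_FV_GAIN * np.log(2.0))
_FV_VCAP = 5.0           # tanh soft cap on |normalized fibre velocity|
_PE_SOFT = 0.01          # softplus width of the passive stretch hinge
_PE_OFFSET = np.expm1(PE_SHAPE * _PE_SOFT * np.log(2.0))
_PE_NORM = np.expm1(PE_SHAPE * 0.6)      # passive force ~1 at l = 1.6
_TAU_BLEND = 0.02        # sigmoid width of the activation tau switch


class ModelDegeneracyError(ValueError):
    """Raised when a muscle's fibre length becomes non-positive."""


def _real(x):
    return x.real if np.iscomplexobj(x) else x


def _attachment(seg: int, cx: float, cy: float, t1, t12, L1):
    """World position of an attachment point and its angle derivatives.

    Returns ``p, dp_dt1, dp_dt2`` each with shape (..., 2).
    """
    zero = np.zeros_like(t1)
    if seg == GROUND:
        p = np.stack((cx + zero, cy + zero), axis=-1)
        z2 = np.stack((zero, zero), axis=-1)
        return p, z2, z2
    if seg == UPPER_ARM:
        c, s = np.cos(t1), np.sin(t1)
        p = np.stack((cx * c - cy * s, cx * s + cy * c), axis=-1)
        dp1 = np.stack((-cx * s - cy * c, cx * c - cy * s), axis=-1)
        z2 = np.stack((zero, zero), axis=-1)
        return p, dp1, z2
    # forearm
    c1, s1 = np.cos(t1), np.sin(t1)
    c12, s12 = np.cos(t12), np.sin(t12)
    p = np.stack((L1 * c1 + cx * c12 - cy * s12,
                  L1 * s1 + cx * s12 + cy * c12), axis=-1)
    dp2 = np.stack((-cx * s12 - cy * c12, cx * c12 - cy * s12), axis=-1)
    dp1 = np.stack((-L1 * s1, L1 * c1), axis=-1) + dp2
    return p, dp1, dp2


def musculotendon_geometry(theta1, theta2, arm: ArmParameters,
                           muscles: MuscleSet):
    """Musculotendon path lengths and moment arms at a posture.

    Returns ``(lengths, moment_arms)`` with shapes (..., 6) and (..., 2, 6);
    ``moment_arms[..., j, m] = -dL_m/dtheta_j``, the standard tendon-excursion
    moment arm, positive when muscle ``m`` produces positive (flexion) torque
    about joint ``j``.  Derivatives are analytic (exact differentiation of the
    straight-line geometry).
    """
    t1 = np.asarray(theta1)
    t2 = np.asarray(theta2)
    if not (np.all(np.isfinite(_real(t1))) and np.all(np.isfinite(_real(t2)))):
        raise ValueError("non-finite joint angles")
    t12 = t1 + t2
    L1 = arm.upper_arm_length
    lengths, arms1, arms2 = [], [], []
    for m in range(6):
        po, do1, do2 = _attachment(int(muscles.origin_segment[m]),
                                   *muscles.origin_xy[m], t1, t12, L1)
        pi, di1, di2 = _attachment(int(muscles.insertion_segment[m]),
                                   *muscles.insertion_xy[m], t1, t12, L1)
        d = pi - po
        L = np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)
        dL1 = (d * (di1 - do1)).sum(axis=-1) / L
        dL2 = (d * (di2 - do2)).sum(axis=-1) / L
        lengths.append(L)
        arms1.append(-dL1)
        arms2.append(-dL2)
    lengths = np.stack(lengths, axis=-1)
    R = np.stack((np.stack(arms1, axis=-1), np.stack(arms2, axis=-1)), axis=-2)
    return lengths, R


def muscle_geometry(q, arm: ArmParameters, muscles: MuscleSet):
    """Convenience wrapper taking a joint-angle pair ``q = (theta1, theta2)``."""
    q = np.asarray(q)
    return musculotendon_geometry(q[..., 0], q[..., 1], arm, muscles)


# -- Hill curves ------------------------------------------------------------

def active_force_length(lnorm):
    return np.exp(-((lnorm - 1.0) / FL_WIDTH) ** 2)


def force_velocity(vnorm):
    """Force-velocity multiplier; ``vnorm`` is fibre velocity over v_max.

    Shortening is negative.  A single analytic Hill-like curve,

        f_V(v) = 1.4 - 0.4 * exp(-k * sp_w(v)),
        sp_w(v) = w * log((1 + exp(v / w)) / 2),

    with k = 2 * (1 + 1/a_f) and the softplus width w set so the curve
    vanishes at full-speed shortening: exactly 1 at v = 0 with slope
    1 + 1/a_f, monotone, ~0 at v = -1, saturating at the 1.4 eccentric
    plateau.  The velocity argument is soft-capped with a tanh so extreme
    optimizer iterates stay bounded; being analytic (no piecewise switch)
    keeps direct collocation at design order.
    """
    v = np.asarray(vnorm)
    v = _FV_VCAP * np.tanh(v / _FV_VCAP)
    sp = _softplus(v, _FV_SOFT) - _FV_SOFT * np.log(2.0)
    return FV_ECC_PLATEAU - (FV_ECC_PLATEAU - 1.0) * np.exp(-_FV_GAIN * sp)


def _softplus(s, eps):
    # numerically stable eps*log(1 + exp(s/eps)); both branches are the same
    # analytic function, so the switch does not break smoothness
    sr = _real(np.asarray(s))
    big = sr > 0
    pos = np.where(big, s, 0.0 * s)
    neg = np.where(big, 0.0 * s, s)
    return np.where(big,
                    pos + eps * np.log1p(np.exp(-pos / eps)),
                    eps * np.log1p(np.exp(neg / eps)))


def passive_force_length(lnorm):
    l = np.asarray(lnorm)
    stretch = _softplus(l - 1.0, _PE_SOFT)
    return (np.expm1(PE_SHAPE * stretch) - _PE_OFFSET) / _PE_NORM


def fiber_state(lengths, velocities, muscles: MuscleSet):
    """Normalized fibre lengths and velocities from musculotendon quantities."""
    cosp = muscles.cos_pennation
    lf = (lengths - muscles.tendon_slack) / cosp
    lopt = muscles.optimal_fiber
    lnorm = lf / lopt
    vnorm = (velocities / cosp) / (VMAX_SCALE * lopt)
    return lnorm, vnorm


def tendon_forces(a, lengths, velocities, muscles: MuscleSet, guard: bool = True):
    """Tendon forces (N, >= 0) for all six muscles, vectorized.

    ``a`` are activations (..., 6); ``lengths``/``velocities`` the
    musculotendon path lengths (m) and lengthening rates (m/s).  With
    ``guard`` (default) non-physical fibre lengths encountered by optimizer
    iterates are floored rather than raised.
    """
    lnorm, vnorm = fiber_state(lengths, velocities, muscles)
    if guard:
        lnorm = np.where(_real(lnorm) < 1e-3, 1e-3, lnorm)
    f = muscles.f0max * muscles.cos_pennation * (
        a * active_force_length(lnorm) * force_velocity(vnorm)
        + passive_force_length(lnorm))
    return np.where(_real(f) < 0.0, 0.0 * f, f)


def muscle_force(a: float, muscle_index: int, q, qdot,
                 arm: ArmParameters, muscles: MuscleSet) -> float:
    """Tendon force (N) of one muscle at activation ``a`` and state (q, q̇).

    Raises :class:`ModelDegeneracyError` if the fibre length is non-positive
    at the requested posture.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    lengths, R = muscle_geometry(np.asarray(q, dtype=float), arm, muscles)
    qd = np.asarray(qdot, dtype=float)
    velocities = -(R[0] * qd[0] + R[1] * qd[1])
    m = muscle_index
    lf = (lengths[m] - muscles.tendon_slack[m]) / muscles.cos_pennation[m]
    if lf <= 0:
        raise ModelDegeneracyError(
            f"fibre length of muscle {muscles.names[m]!r} is non-positive "
            f"({lf:.4g} m) at this posture")
    act = np.zeros(6)
    act[m] = a
    return float(tendon_forces(act, lengths, velocities, muscles, guard=False)[m])


def activation_rate(a, u, muscles: MuscleSet):
    """First-order excitation-to-activation rate da/dt (1/s), vectorized.

    The time constant switches between the activation constant (when the
    excitation exceeds the current activation) and the slower deactivation
    constant; the fixed point is a = u.
    """
    a = np.asarray(a)
    u = np.asarray(u)
    # sigmoid blend of the two time constants around u = a (width _TAU_BLEND)
    w = 1.0 / (1.0 + np.exp(-(u - a) / _TAU_BLEND))
    rate = w / muscles.tau_act + (1.0 - w) / muscles.tau_deact
    return (u - a) * rate


def activation_dynamics(a, u, muscles: MuscleSet):
    """Spec-facing alias of :func:`activation_rate` with input validation."""
    a = np.asarray(a, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("activations must lie in [0, 1]")
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("excitations must lie in [0, 1]")
    return activation_rate(a, u, muscles)
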