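"""Direct-collocation transcription and solution of finite-horizon OCPs.

A single horizon problem — minimize the integral of a tracking-plus-effort
running cost, subject to the arm dynamics, excitation bounds and (optionally)
a terminal state equality — is transcribed to a nonlinear program by
Legendre-Gauss-Radau (LGR) collocation: the horizon is split into K equal
intervals and, within each, states and controls are parameterized by Lagrange
polynomials on the flipped-Radau nodes (right endpoint included).  The
dynamics are enforced as defect constraints at the collocation points and the
cost by the scheme's quadrature.  Both the receding-horizon controller and
the fixed-final-time dynamic optimization build on this module.

The NLP is solved by the package's primal-dual interior-point SQP (scipy's
SLSQP remains available as an alternative engine), fed exact first
derivatives: the dynamics Jacobians at the collocation points are obtained
by complex-step differentiation and assembled into the sparse defect
structure, and the objective gradient is analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from numpy.polynomial import legendre as npleg
from numpy.polynomial.polynomial import Polynomial
from scipy.optimize import minimize

from .arm import forward_kinematics, hand_jacobian
from .dynamics import dynamics_jacobians, dynamics_vec
from .params import ArmParameters, MuscleSet, SystemState

DEFAULT_INTERVALS = 25
DEFAULT_DEGREE = 3
FEASIBILITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# collocation scheme


@lru_cache(maxsize=None)
def radau_scheme(d: int):
    """Flipped-LGR nodes, differentiation matrix and quadrature weights.

    Returns ``(c, D, w)``: collocation nodes ``c`` (shape d, in (0, 1], last
    node exactly 1), differentiation matrix ``D`` (d x (d+1), columns indexed
    by the interpolation nodes {0} + c) and quadrature weights ``w`` (d,
    integrating exactly polynomials of degree 2d-2 on [0, 1]).
    """
    if not 2 <= d <= 10:
        raise ValueError("collocation degree must be in [2, 10]")
    # left-Radau points on [-1, 1]: roots of P_{d-1} + P_d  (includes -1)
    coeffs = np.zeros(d + 1)
    coeffs[d - 1] = 1.0
    coeffs[d] = 1.0
    roots = npleg.legroots(coeffs)
    c = np.sort((1.0 - roots) / 2.0)          # flip and map to (0, 1]
    c[-1] = 1.0
    nodes = np.concatenate(([0.0], c))        # interpolation nodes
    D = np.empty((d, d + 1))
    w = np.empty(d)
    for j in range(d + 1):
        lj = Polynomial([1.0])
        for m in range(d + 1):
            if m != j:
                lj *= Polynomial([-nodes[m], 1.0]) / (nodes[j] - nodes[m])
        dlj = lj.deriv()
        D[:, j] = dlj(c)
    for i in range(d):
        li = Polynomial([1.0])
        for m in range(1, d + 1):
            if m != i + 1:
                li *= Polynomial([-nodes[m], 1.0]) / (nodes[i + 1] - nodes[m])
        w[i] = li.integ()(1.0) - li.integ()(0.0)
    return c, D, w


def _lagrange_eval(nodes: np.ndarray, values: np.ndarray, tau):
    """Evaluate the Lagrange interpolant through (nodes, values) at tau.

    ``values`` has shape (len(nodes), nc); ``tau`` scalar or (nt,).  Returns
    (nc,) or (nt, nc).
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    n = len(nodes)
    basis = np.ones((tau.size, n))
    for j in range(n):
        for m in range(n):
            if m != j:
                basis[:, j] *= (tau - nodes[m]) / (nodes[j] - nodes[m])
    out = basis @ values
    return out


# ---------------------------------------------------------------------------
# problem containers


@dataclass
class MeshSpec:
    intervals: int = DEFAULT_INTERVALS
    degree: int = DEFAULT_DEGREE

    def __post_init__(self) -> None:
        if self.intervals < 1:
            raise ValueError("mesh must have at least one interval")
        if not 2 <= self.degree <= 10:
            raise ValueError("collocation degree must be in [2, 10]")

    def refined(self) -> "MeshSpec":
        """Uniformly refined mesh (K -> 2K)."""
        return MeshSpec(2 * self.intervals, self.degree)


@dataclass
class OcpProblem:
    """One finite-horizon optimal control problem.

    ``target`` is the desired hand position: a constant planar point or a
    callable ``t -> (2,)`` for time-varying references.  ``tracking_weight``
    (p) and ``effort_weight`` (q) weight the squared hand-position error and
    the summed squared excitations in the running cost.  ``terminal_state``
    with ``terminal_mask`` imposes equality on the masked state components at
    the end of the horizon; ``terminal_cost`` is the optional end-point cost
    hook (disabled by default, as in the goal-directed formulation).
    """

    t0: float
    horizon: float
    x0: np.ndarray
    tracking_weight: float = 20.0
    effort_weight: float = 1.0
    target: object = None
    terminal_state: np.ndarray | None = None
    terminal_mask: np.ndarray | None = None
    terminal_cost: Callable | None = None
    mesh: MeshSpec = field(default_factory=MeshSpec)
    u_min: float = 0.0
    u_max: float = 1.0
    angle_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ValueError("horizon length must be positive")
        if self.tracking_weight < 0 or self.effort_weight < 0:
            raise ValueError("cost weights must be non-negative")
        if self.tracking_weight == 0 and self.effort_weight == 0 \
                and self.terminal_state is None:
            raise ValueError("cost weights must not both be zero")
        if isinstance(self.x0, SystemState):
            self.x0 = self.x0.as_vector()
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (10,):
            raise ValueError("x0 must be a 10-vector")
        if self.terminal_state is not None:
            self.terminal_state = np.asarray(self.terminal_state, dtype=float)
            if self.terminal_mask is None:
                self.terminal_mask = np.ones(10, dtype=bool)
            self.terminal_mask = np.asarray(self.terminal_mask, dtype=bool)

    def to_yaml(self, path) -> None:
        """Serialize to YAML.  Only constant point targets are representable;
        time-varying target callables are rejected."""
        import yaml
        from pathlib import Path

        if callable(self.target) or callable(self.terminal_cost):
            raise ValueError("only constant-target problems without a "
                             "terminal-cost hook are YAML-serializable")
        doc = {
            "t0_s": float(self.t0),
            "horizon_s": float(self.horizon),
            "x0": [float(v) for v in self.x0],
            "tracking_weight": float(self.tracking_weight),
            "effort_weight": float(self.effort_weight),
            "target_m": None if self.target is None
            else [float(v) for v in np.asarray(self.target)],
            "terminal_state": None if self.terminal_state is None
            else [float(v) for v in self.terminal_state],
            "terminal_mask": None if self.terminal_state is None
            else [bool(v) for v in self.terminal_mask],
            "mesh": {"intervals": self.mesh.intervals,
                     "degree": self.mesh.degree},
            "u_min": float(self.u_min),
            "u_max": float(self.u_max),
            "angle_bounds": None if self.angle_bounds is None
            else [float(v) for v in self.angle_bounds],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "OcpProblem":
        import yaml
        from pathlib import Path

        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            t0=doc["t0_s"], horizon=doc["horizon_s"],
            x0=np.asarray(doc["x0"], dtype=float),
            tracking_weight=doc["tracking_weight"],
            effort_weight=doc["effort_weight"],
            target=None if doc["target_m"] is None
            else np.asarray(doc["target_m"], dtype=float),
            terminal_state=None if doc["terminal_state"] is None
            else np.asarray(doc["terminal_state"], dtype=float),
            terminal_mask=None if doc.get("terminal_mask") is None
            else np.asarray(doc["terminal_mask"], dtype=bool),
            mesh=MeshSpec(doc["mesh"]["intervals"], doc["mesh"]["degree"]),
            u_min=doc.get("u_min", 0.0), u_max=doc.get("u_max", 1.0),
            angle_bounds=None if doc.get("angle_bounds") is None
            else tuple(doc["angle_bounds"]))

    def target_at(self, t):
        """Desired hand position at time(s) t, shape (..., 2)."""
        if callable(self.target):
            t = np.asarray(t, dtype=float)
            if t.ndim == 0:
                return np.asarray(self.target(float(t)), dtype=float)
            return np.stack([np.asarray(self.target(float(ti)), dtype=float)
                             for ti in t])
        if self.target is None:
            return np.zeros(np.shape(t) + (2,)) if np.ndim(t) else np.zeros(2)
        tgt = np.asarray(self.target, dtype=float)
        return np.broadcast_to(tgt, np.shape(t) + (2,)).copy() \
            if np.ndim(t) else tgt


# ---------------------------------------------------------------------------
# costs


def effort_cost(u) -> float:
    """Summed squared neural excitation over the six muscles, u -> sum u_i^2."""
    u = np.asarray(u)
    return (u * u).sum(axis=-1)


def running_cost(x, u, spec: OcpProblem, t, arm: ArmParameters):
    """Tracking-plus-effort integrand p ||zeta - zeta_des(t)||^2 + q sum u^2."""
    x = np.asarray(x)
    zeta = forward_kinematics(x[..., 0:2], arm)
    err = zeta - spec.target_at(t)
    return (spec.tracking_weight * (err * err).sum(axis=-1)
            + spec.effort_weight * effort_cost(u))


# ---------------------------------------------------------------------------
# transcription


class CollocationNlp:
    """The transcribed NLP: decision-vector layout, cost, constraints, bounds.

    Layout: ``z = [vec(X), vec(U)]`` with ``X`` the states at the K*d
    collocation nodes (row-major node, state) and ``U`` the controls at the
    same nodes.  The initial state is a constant, not a decision variable;
    interval continuity is implicit because the last Radau node of each
    interval is its right endpoint.
    """

    def __init__(self, spec: OcpProblem, arm: ArmParameters,
                 muscles: MuscleSet):
        self.spec = spec
        self.arm = arm
        self.muscles = muscles
        K, d = spec.mesh.intervals, spec.mesh.degree
        self.K, self.d = K, d
        self.N = K * d                       # collocation nodes
        self.nx, self.nu = 10, 6
        self.n = self.N * (self.nx + self.nu)
        self.h = spec.horizon / K
        c, D, w = radau_scheme(d)
        self.c, self.D, self.w = c, D, w
        # absolute times of the collocation nodes
        self.t_nodes = (spec.t0
                        + (np.repeat(np.arange(K), d) + np.tile(c, K)) * self.h)
        self.targets = spec.target_at(self.t_nodes)     # (N, 2)
        self.n_defect = self.N * self.nx
        self.n_terminal = (int(spec.terminal_mask.sum())
                           if spec.terminal_state is not None else 0)
        self.m = self.n_defect + self.n_terminal
        self._linear = self._build_linear_defect_matrix()
        self._build_sparse_structure()
        self._cache_key = None
        self._cache = None
        self._jac_key = None
        self._jac = None
        self._sjac_key = None
        self._sjac = None

    # -- layout helpers ---------------------------------------------------

    def split(self, z: np.ndarray):
        X = z[:self.N * self.nx].reshape(self.N, self.nx)
        U = z[self.N * self.nx:].reshape(self.N, self.nu)
        return X, U

    def pack(self, X: np.ndarray, U: np.ndarray) -> np.ndarray:
        return np.concatenate((X.reshape(-1), U.reshape(-1)))

    def bounds(self) -> list[tuple[float | None, float | None]]:
        bx: list[tuple[float | None, float | None]] = []
        ab = self.spec.angle_bounds
        for _ in range(self.N):
            for i in range(self.nx):
                if i < 2 and ab is not None:
                    bx.append((ab[0], ab[1]))
                elif i >= 4:
                    bx.append((0.0, 1.0))     # activation states
                else:
                    bx.append((None, None))
        bu = [(self.spec.u_min, self.spec.u_max)] * (self.N * self.nu)
        return bx + bu

    def initial_guess(self, u_level: float = 0.01) -> np.ndarray:
        """Cold start: states held at x0, controls at a small interior level."""
        X = np.tile(self.spec.x0, (self.N, 1))
        U = np.full((self.N, self.nu), u_level)
        return self.pack(X, U)

    # -- evaluation -------------------------------------------------------

    def _build_linear_defect_matrix(self) -> np.ndarray:
        """Constant part of the defect Jacobian w.r.t. the state variables."""
        K, d, nx = self.K, self.d, self.nx
        L = np.zeros((self.n_defect, self.N * nx))
        I = np.eye(nx)
        for k in range(K):
            for i in range(d):
                row = (k * d + i) * nx
                for j in range(1, d + 1):
                    col = (k * d + j - 1) * nx
                    L[row:row + nx, col:col + nx] += self.D[i, j] * I
                if k > 0:
                    col = (k * d - 1) * nx    # previous interval's end node
                    L[row:row + nx, col:col + nx] += self.D[i, 0] * I
        return L

    def _build_sparse_structure(self) -> None:
        """Precompute index arrays for the sparse Jacobian and GN Hessian."""
        import scipy.sparse as sp

        N, nx, nu = self.N, self.nx, self.nu
        lin = sp.coo_matrix(self._linear)
        self._lin_rows, self._lin_cols = lin.row, lin.col
        self._lin_data = lin.data
        node = np.arange(N)
        # dynamics blocks: rows (N,10,16), state cols then control cols
        r = (node[:, None, None] * nx
             + np.arange(nx)[None, :, None]) * np.ones((1, 1, nx + nu), int)
        cx = node[:, None, None] * nx + np.arange(nx)[None, None, :] \
            * np.ones((1, nx, 1), int)
        cu = N * nx + node[:, None, None] * nu + np.arange(nu)[None, None, :] \
            * np.ones((1, nx, 1), int)
        self._dyn_rows = r.reshape(-1)
        self._dyn_cols = np.concatenate((cx, cu), axis=2).reshape(-1)
        if self.n_terminal:
            mask_idx = np.flatnonzero(self.spec.terminal_mask)
            self._term_rows = self.n_defect + np.arange(self.n_terminal)
            self._term_cols = (N - 1) * nx + mask_idx
        else:
            self._term_rows = np.empty(0, int)
            self._term_cols = np.empty(0, int)
        # GN Hessian: 2x2 angle block per node + control diagonal
        self._hess_rows = np.concatenate((
            (node[:, None, None] * nx
             + np.array([[0, 0], [1, 1]])[None]).reshape(-1),
            N * nx + np.arange(N * nu)))
        self._hess_cols = np.concatenate((
            (node[:, None, None] * nx
             + np.array([[0, 1], [0, 1]])[None]).reshape(-1),
            N * nx + np.arange(N * nu)))
        self._wN = np.tile(self.w, self.K) * self.h

    def variable_scales(self) -> np.ndarray:
        """Typical magnitudes of the decision variables (for step damping)."""
        sx = np.tile(np.array([1.0, 1.0, 5.0, 5.0, 1, 1, 1, 1, 1, 1]), self.N)
        su = np.ones(self.N * self.nu)
        return np.concatenate((sx, su))

    def node_partitions(self) -> list[np.ndarray]:
        """Index sets of variables that interact nonlinearly (one per node)."""
        out = []
        for i in range(self.N):
            out.append(np.concatenate((
                i * self.nx + np.arange(self.nx),
                self.N * self.nx + i * self.nu + np.arange(self.nu))))
        return out

    def sparse_jacobian(self, z: np.ndarray):
        """Constraint Jacobian as a CSC sparse matrix."""
        import scipy.sparse as sp

        key = z.tobytes()
        if key == self._sjac_key:
            return self._sjac
        X, U = self.split(z)
        A, B = dynamics_jacobians(X, U, self.arm, self.muscles)
        dyn = -self.h * np.concatenate((A, B), axis=2).reshape(-1)
        rows = np.concatenate((self._lin_rows, self._dyn_rows,
                               self._term_rows))
        cols = np.concatenate((self._lin_cols, self._dyn_cols,
                               self._term_cols))
        data = np.concatenate((self._lin_data, dyn,
                               np.ones(self.n_terminal)))
        J = sp.coo_matrix((data, (rows, cols)), shape=(self.m, self.n))
        self._sjac_key = key
        self._sjac = J.tocsc()
        return self._sjac

    def gn_hessian(self, z: np.ndarray):
        """Gauss-Newton Hessian of the objective (sparse PSD)."""
        import scipy.sparse as sp

        X, _ = self.split(z)
        Jh = hand_jacobian(X[:, 0:2], self.arm)           # (N, 2, 2)
        blocks = 2.0 * self.spec.tracking_weight * self._wN[:, None, None] \
            * np.einsum("nki,nkj->nij", Jh, Jh)
        du = 2.0 * self.spec.effort_weight * np.repeat(self._wN, self.nu)
        data = np.concatenate((blocks.reshape(-1), du))
        return sp.coo_matrix((data, (self._hess_rows, self._hess_cols)),
                             shape=(self.n, self.n)).tocsc()

    def _point_data(self, z: np.ndarray):
        key = z.tobytes()
        if key == self._cache_key:
            return self._cache
        X, U = self.split(z)
        f = dynamics_vec(X, U, self.arm, self.muscles)      # (N, 10)
        # defects
        defect = self._linear @ z[:self.N * self.nx] - self.h * f.reshape(-1)
        d0 = np.zeros(self.n_defect)
        # contribution of the constant initial state to the first interval
        for i in range(self.d):
            d0[i * self.nx:(i + 1) * self.nx] = self.D[i, 0] * self.spec.x0
        defect[:self.d * self.nx] += d0[:self.d * self.nx]
        cons = defect
        if self.n_terminal:
            mask = self.spec.terminal_mask
            cons = np.concatenate(
                (defect, X[-1, mask] - self.spec.terminal_state[mask]))
        # cost and gradient
        spec = self.spec
        zeta = forward_kinematics(X[:, 0:2], self.arm)
        err = zeta - self.targets
        wN = np.tile(self.w, self.K) * self.h            # quadrature weights
        track = (err * err).sum(axis=1)
        eff = (U * U).sum(axis=1)
        J = float(wN @ (spec.tracking_weight * track + spec.effort_weight * eff))
        grad = np.zeros(self.n)
        Jh = hand_jacobian(X[:, 0:2], self.arm)          # (N, 2, 2)
        dq = 2.0 * spec.tracking_weight * np.einsum(
            "ni,nij->nj", err, Jh) * wN[:, None]
        gX = np.zeros((self.N, self.nx))
        gX[:, 0:2] = dq
        gU = 2.0 * spec.effort_weight * U * wN[:, None]
        grad[:self.N * self.nx] = gX.reshape(-1)
        grad[self.N * self.nx:] = gU.reshape(-1)
        if spec.terminal_cost is not None:
            xf = X[-1]
            eps = 1e-30
            base = float(spec.terminal_cost(xf))
            J += base
            xc = xf.astype(complex)
            for j in range(self.nx):
                xc[j] += 1j * eps
                grad[(self.N - 1) * self.nx + j] += \
                    complex(spec.terminal_cost(xc)).imag / eps
                xc[j] = xf[j]
        self._cache_key = key
        self._cache = (J, grad, cons)
        return self._cache

    def objective(self, z: np.ndarray) -> float:
        return self._point_data(z)[0]

    def gradient(self, z: np.ndarray) -> np.ndarray:
        return self._point_data(z)[1]

    def constraints(self, z: np.ndarray) -> np.ndarray:
        return self._point_data(z)[2]

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        key = z.tobytes()
        if key == self._jac_key:
            return self._jac
        X, U = self.split(z)
        A, B = dynamics_jacobians(X, U, self.arm, self.muscles)
        J = np.zeros((self.m, self.n))
        J[:self.n_defect, :self.N * self.nx] = self._linear
        nx, nu = self.nx, self.nu
        for nidx in range(self.N):
            r = nidx * nx
            J[r:r + nx, nidx * nx:(nidx + 1) * nx] -= self.h * A[nidx]
            cu = self.N * nx + nidx * nu
            J[r:r + nx, cu:cu + nu] = -self.h * B[nidx]
        if self.n_terminal:
            mask_idx = np.flatnonzero(self.spec.terminal_mask)
            for r, j in enumerate(mask_idx):
                J[self.n_defect + r, (self.N - 1) * nx + j] = 1.0
        self._jac_key = key
        self._jac = J
        return J

    def defect_residual(self, z: np.ndarray) -> float:
        return float(np.abs(self._point_data(z)[2][:self.n_defect]).max())


def transcribe(spec: OcpProblem, arm: ArmParameters,
               muscles: MuscleSet) -> CollocationNlp:
    """Build the collocation NLP for a horizon problem."""
    return CollocationNlp(spec, arm, muscles)


# ---------------------------------------------------------------------------
# solution container


@dataclass
class OcpSolution:
    """Discretized optimal trajectories over one horizon, with interpolants."""

    t0: float
    horizon: float
    intervals: int
    degree: int
    times: np.ndarray            # node times incl. t0, shape (1 + K*d,)
    states: np.ndarray           # (1 + K*d, 10), row 0 is x0
    controls: np.ndarray         # (K*d, 6)
    objective: float
    success: bool
    message: str
    n_iter: int
    defect_max: float

    @property
    def h(self) -> float:
        return self.horizon / self.intervals

    @property
    def usable(self) -> bool:
        """Whether the trajectories are dynamically consistent enough to
        apply: formally converged, or feasible to 1e-5 with the optimizer
        stopped short of its duals tolerance (the cost surface of these
        problems is flat in the co-contraction directions, so near-feasible
        stalls are still physically meaningful solutions)."""
        return self.success or self.defect_max <= 1e-5

    def _locate(self, t):
        # at interval boundaries use the left interval: its last Radau node
        # lies exactly on the boundary, so both state and control
        # interpolants are continuous from the left there
        tau = (np.asarray(t, dtype=float) - self.t0) / self.h
        k = np.clip(np.ceil(tau - 1e-10).astype(int) - 1,
                    0, self.intervals - 1)
        return k, tau - k

    def interp_x(self, t):
        """State interpolant (degree-d polynomial per interval)."""
        c, _, _ = radau_scheme(self.degree)
        nodes = np.concatenate(([0.0], c))
        k, loc = self._locate(t)
        scalar = np.ndim(t) == 0
        k, loc = np.atleast_1d(k), np.atleast_1d(loc)
        out = np.empty((k.size, 10))
        for kk in np.unique(k):
            sel = k == kk
            vals = np.vstack((self.states[kk * self.degree][None, :],
                              self.states[kk * self.degree + 1:
                                          (kk + 1) * self.degree + 1]))
            out[sel] = _lagrange_eval(nodes, vals, loc[sel])
        return out[0] if scalar else out

    def interp_u(self, t):
        """Control interpolant (degree d-1 polynomial per interval)."""
        c, _, _ = radau_scheme(self.degree)
        k, loc = self._locate(t)
        scalar = np.ndim(t) == 0
        k, loc = np.atleast_1d(k), np.atleast_1d(loc)
        out = np.empty((k.size, 6))
        for kk in np.unique(k):
            sel = k == kk
            vals = self.controls[kk * self.degree:(kk + 1) * self.degree]
            out[sel] = _lagrange_eval(c, vals, loc[sel])
        clipped = np.clip(out, 0.0, 1.0)
        return clipped[0] if scalar else clipped

    def to_frame(self):
        """Node trajectories as a pandas DataFrame (one row per node)."""
        import pandas as pd

        cols = {"t": self.times}
        for i in range(10):
            cols[f"x{i + 1}"] = self.states[:, i]
        u_full = np.vstack((np.full((1, 6), np.nan), self.controls))
        for i in range(6):
            cols[f"u{i + 1}"] = u_full[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# solving


def _guess_vector(nlp: CollocationNlp,
                  initial_guess: "OcpSolution | np.ndarray | None"):
    spec = nlp.spec
    if initial_guess is None:
        return nlp.initial_guess(), False
    if isinstance(initial_guess, OcpSolution):
        tX = nlp.t_nodes
        X = initial_guess.interp_x(tX)
        X[:, 4:10] = np.clip(X[:, 4:10], 0.0, 1.0)
        U = np.clip(initial_guess.interp_u(tX), spec.u_min, spec.u_max)
        return nlp.pack(X, U), True
    z0 = np.asarray(initial_guess, dtype=float)
    if z0.shape != (nlp.n,):
        raise ValueError("initial guess has wrong length")
    return z0, True


def solve_ocp(spec: OcpProblem, arm: ArmParameters, muscles: MuscleSet,
              initial_guess: OcpSolution | np.ndarray | None = None,
              max_iter: int = 200, tol: float = 1e-7,
              feasibility_tol: float = FEASIBILITY_TOL,
              method: str = "ip") -> OcpSolution:
    """Solve one horizon OCP on the collocation transcription.

    The default engine is the package's interior-point Gauss-Newton solver
    (``method="ip"``); ``method="slsqp"`` uses scipy's SLSQP instead (slower,
    kept as a cross-check and fallback).  ``initial_guess`` may be a previous
    :class:`OcpSolution` — its interpolants are resampled onto this problem's
    mesh, the receding-horizon warm start — or a raw decision vector.  The
    solve is deterministic for identical inputs and settings.
    """
    nlp = transcribe(spec, arm, muscles)
    z0, warm = _guess_vector(nlp, initial_guess)

    if method == "ip":
        from .nlp import solve_interior_point

        lo, hi = zip(*nlp.bounds())
        lb = np.array([-np.inf if v is None else v for v in lo])
        ub = np.array([np.inf if v is None else v for v in hi])
        res = solve_interior_point(
            nlp.objective, nlp.gradient, nlp.constraints,
            nlp.sparse_jacobian, nlp.gn_hessian, lb, ub, z0,
            tol=tol, max_iter=max_iter, warm=warm,
            partitions=nlp.node_partitions(),
            scales=nlp.variable_scales())
        z, fun = res.z, res.objective
        success0, message, nit = res.success, res.message, res.n_iter
    elif method == "slsqp":
        res = minimize(
            nlp.objective, z0, jac=nlp.gradient, method="SLSQP",
            bounds=nlp.bounds(),
            constraints=[{"type": "eq", "fun": nlp.constraints,
                          "jac": nlp.jacobian}],
            options={"maxiter": max(max_iter, 1000), "ftol": 1e-8})
        z, fun = res.x, float(res.fun)
        success0, message, nit = bool(res.success), str(res.message), \
            int(res.get("nit", -1))
    else:
        raise ValueError(f"unknown solver method {method!r}")

    X, U = nlp.split(z)
    U = np.clip(U, spec.u_min, spec.u_max)
    X[:, 4:10] = np.clip(X[:, 4:10], 0.0, 1.0)
    defect = nlp.defect_residual(nlp.pack(X, U))
    success = success0 and defect <= feasibility_tol
    times = np.concatenate(([spec.t0], nlp.t_nodes))
    states = np.vstack((spec.x0[None, :], X))
    return OcpSolution(
        t0=spec.t0, horizon=spec.horizon, intervals=nlp.K, degree=nlp.d,
        times=times, states=states, controls=U,
        objective=float(fun), success=success,
        message=message, n_iter=nit, defect_max=float(defect))
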