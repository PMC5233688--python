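"""A small primal-dual interior-point SQP solver for the collocation NLPs.

Minimizes a smooth objective subject to equality constraints and box bounds:

    min f(z)   s.t.  c(z) = 0,   l <= z <= u

Bounds are handled by a primal-dual log barrier (explicit bound multipliers
with complementarity s·zeta = mu, as in IPOPT), equalities by damped Newton
steps on the barrier KKT system with an l1 exact-penalty line search and a
second-order correction.  The Lagrangian Hessian is approximated by a
partitioned quasi-Newton scheme: the constraint nonlinearity of a collocation
NLP is separable by node (each defect couples the states and controls of one
collocation point nonlinearly; everything else is linear), so a small
Powell-damped BFGS block per node — seeded with the objective's Gauss-Newton
block — captures the curvature while the KKT systems stay sparse.

The solver is deterministic: no randomization, fixed schedules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class NlpResult:
    z: np.ndarray
    multipliers: np.ndarray
    objective: float
    success: bool
    n_iter: int
    kkt_error: float
    constraint_violation: float
    message: str


class _PartitionedHessian:
    """Per-partition Powell-damped BFGS blocks of the Lagrangian Hessian."""

    def __init__(self, partitions: Sequence[np.ndarray], n: int,
                 seed: sp.spmatrix):
        self.parts = [np.asarray(p, dtype=int) for p in partitions]
        self.n = n
        dense_seed = seed.tocsc()
        self.blocks = []
        rows, cols = [], []
        for p in self.parts:
            blk = np.asarray(dense_seed[np.ix_(p, p)].todense())
            blk += 1e-4 * np.eye(p.size)
            self.blocks.append(blk)
            r, c = np.meshgrid(p, p, indexing="ij")
            rows.append(r.reshape(-1))
            cols.append(c.reshape(-1))
        self._rows = np.concatenate(rows)
        self._cols = np.concatenate(cols)

    def matrix(self) -> sp.csc_matrix:
        data = np.concatenate([b.reshape(-1) for b in self.blocks])
        return sp.coo_matrix((data, (self._rows, self._cols)),
                             shape=(self.n, self.n)).tocsc()

    def update(self, dz: np.ndarray, y: np.ndarray) -> None:
        """Powell-damped BFGS update of every block from a full-space pair."""
        for blk, p in zip(self.blocks, self.parts):
            s = dz[p]
            yp = y[p]
            if float(s @ s) < 1e-24:
                continue
            Bs = blk @ s
            sBs = float(s @ Bs)
            sy = float(s @ yp)
            if sBs <= 0:
                continue
            if sy < 0.2 * sBs:   # Powell damping keeps blocks positive
                theta = 0.8 * sBs / (sBs - sy)
                yp = theta * yp + (1.0 - theta) * Bs
                sy = float(s @ yp)
            if sy <= 1e-14:
                continue
            blk += np.outer(yp, yp) / sy - np.outer(Bs, Bs) / sBs


def _eval_hessian(hessian: Callable, z: np.ndarray, lam: np.ndarray):
    """Call a Hessian model; it may or may not take the multipliers."""
    try:
        return hessian(z, lam)
    except TypeError:
        return hessian(z)


def _ftb(s, ds, tau=0.995):
    """Fraction-to-boundary step bound keeping s + a*ds >= (1-tau)*s > 0."""
    shrink = ds < 0
    if not np.any(shrink):
        return 1.0
    return float(min(1.0, (tau * (-s[shrink] / ds[shrink])).min()))


def solve_interior_point(objective: Callable, gradient: Callable,
                         constraints: Callable, jacobian: Callable,
                         hessian: Callable,
                         lb, ub, z0, tol: float = 1e-7,
                         mu0: float = 1e-3,
                         max_iter: int = 300,
                         warm: bool = False,
                         partitions: Sequence[np.ndarray] | None = None,
                         scales: np.ndarray | None = None,
                         verbose: bool = False) -> NlpResult:
    """Solve the NLP; see the module docstring for the problem form.

    ``hessian`` returns a sparse PSD approximation of the objective Hessian
    (the Gauss-Newton seed; it may optionally accept the equality multipliers
    as a second argument); ``jacobian(z)`` the sparse constraint Jacobian.
    ``partitions`` lists index sets of variables that interact nonlinearly
    (one per collocation node); when given, per-block BFGS curvature is
    accumulated on top of the seed.  With ``warm=True`` the barrier parameter
    starts small — the right regime when ``z0`` is a shifted previous
    solution.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    has_lb = np.isfinite(lb)
    has_ub = np.isfinite(ub)
    n = z0.size
    mu = 1e-6 if warm else mu0
    mu_min = min(1e-9, 0.1 * tol)
    # start strictly inside the box, at a distance commensurate with the
    # initial barrier parameter (bound-riding starts otherwise stall)
    width = np.where(has_lb & has_ub, ub - lb, 1.0)
    margin = np.minimum(0.1 * width, np.maximum(1e-8, mu))
    z = np.clip(z0, np.where(has_lb, lb + margin, -np.inf),
                np.where(has_ub, ub - margin, np.inf)).astype(float)

    c = constraints(z)
    m = c.size
    lam = np.zeros(m)
    zL = np.where(has_lb, mu / np.maximum(z - lb, 1e-12), 0.0)
    zU = np.where(has_ub, mu / np.maximum(ub - z, 1e-12), 0.0)
    f = objective(z)
    g = gradient(z)
    nu = 1.0                         # merit penalty on ||c||_1
    delta = 1e-8 if warm else 1e-4   # adaptive Levenberg damping
    # damping acts as delta * I in the scaled space z / scales
    dvec = np.ones(n) if scales is None else 1.0 / np.asarray(scales) ** 2
    pending = None                   # (dz_step, gl_old) for the BFGS pair
    bfgs = _PartitionedHessian(partitions, n,
                               _eval_hessian(hessian, z, lam)) \
        if partitions is not None else None
    n_iter = 0
    message = "maximum iterations reached"
    success = False
    kkt = np.inf
    stall = 0                        # consecutive feasible no-progress steps

    def barrier_value(z_, mu_):
        sL_ = z_[has_lb] - lb[has_lb]
        sU_ = ub[has_ub] - z_[has_ub]
        if np.any(sL_ <= 0) or np.any(sU_ <= 0):
            return np.inf
        return -mu_ * (np.log(sL_).sum() + np.log(sU_).sum())

    while n_iter < max_iter:
        n_iter += 1
        sL = np.where(has_lb, z - lb, 1.0)
        sU = np.where(has_ub, ub - z, 1.0)
        # keep dual variables in a cone around mu/s (IPOPT's kappa-Sigma)
        kap = 1e10
        zL = np.where(has_lb, np.clip(zL, mu / (kap * sL), kap * mu / sL), 0.0)
        zU = np.where(has_ub, np.clip(zU, mu / (kap * sU), kap * mu / sU), 0.0)

        J = jacobian(z)
        gl = g + J.T @ lam
        if bfgs is not None and pending is not None:
            dz_step, gl_old = pending
            bfgs.update(dz_step, gl - gl_old)
            pending = None
        H = bfgs.matrix() if bfgs is not None \
            else _eval_hessian(hessian, z, lam)

        dual_res = gl - zL + zU
        comp_L = np.abs(sL * zL - mu)[has_lb]
        comp_U = np.abs(sU * zU - mu)[has_ub]
        kkt_mu = max(np.abs(dual_res).max(initial=0.0),
                     np.abs(c).max(initial=0.0),
                     comp_L.max(initial=0.0), comp_U.max(initial=0.0))
        # error for the original problem: mu bounds the complementarity gap
        kkt = max(np.abs(dual_res).max(initial=0.0),
                  np.abs(c).max(initial=0.0), mu)
        if kkt <= tol:
            success = True
            message = "converged"
            break
        if kkt_mu <= 10.0 * mu and mu > mu_min:
            mu = max(mu_min, min(mu / 10.0, mu ** 1.4))
            continue

        sigma = np.where(has_lb, zL / sL, 0.0) + np.where(has_ub, zU / sU, 0.0)
        grad_phi = g - np.where(has_lb, mu / sL, 0.0) \
            + np.where(has_ub, mu / sU, 0.0)

        lu = None
        for _ in range(6):
            K = sp.bmat([[H + sp.diags(sigma + delta * dvec), J.T],
                         [J, -1e-10 * sp.identity(m)]], format="csc")
            rhs = np.concatenate((-grad_phi, -c))
            try:
                lu = spla.splu(K)
                sol = lu.solve(rhs)
            except RuntimeError:
                delta = max(1e-6, delta * 100.0)
                continue
            if np.all(np.isfinite(sol)):
                break
            delta = max(1e-6, delta * 100.0)
        else:
            message = "linear solver failure"
            break
        dz = sol[:n]
        lam_new = sol[n:]
        dzL = np.where(has_lb, mu / sL - zL - zL / sL * dz, 0.0)
        dzU = np.where(has_ub, mu / sU - zU + zU / sU * dz, 0.0)

        alpha_max = min(_ftb(sL[has_lb], dz[has_lb]),
                        _ftb(sU[has_ub], -dz[has_ub]))
        alpha_dual = min(_ftb(zL[has_lb], dzL[has_lb]),
                         _ftb(zU[has_ub], dzU[has_ub]))

        # exact-penalty weight tracks the multipliers both ways; a monotone
        # weight would keep rejecting good steps after a transient spike
        nu = max(1.2 * np.abs(lam_new).max(initial=0.0), 1.0)
        phi0 = f + barrier_value(z, mu) + nu * np.abs(c).sum()
        ddir = grad_phi @ dz - nu * np.abs(c).sum()

        def merit(z_try, c_try, f_try):
            return f_try + barrier_value(z_try, mu) + nu * np.abs(c_try).sum()

        alpha = alpha_max
        accepted = False
        soc_tried = False
        for _ in range(30):
            z_try = z + alpha * dz
            c_try = constraints(z_try)
            f_try = objective(z_try)
            phi = merit(z_try, c_try, f_try)
            if np.isfinite(phi) and phi <= phi0 + 1e-4 * alpha * min(ddir, 0.0):
                accepted = True
                break
            if not soc_tried and alpha == alpha_max:
                # second-order correction: cancel curvature-induced
                # infeasibility reusing the same KKT factorization
                soc_tried = True
                dz2 = lu.solve(np.concatenate((np.zeros(n), -c_try)))[:n]
                a2 = min(_ftb(sL[has_lb] - alpha * (-dz[has_lb]),
                              dz2[has_lb]) if np.any(has_lb) else 1.0,
                         _ftb(sU[has_ub] + alpha * (-dz[has_ub]),
                              -dz2[has_ub]) if np.any(has_ub) else 1.0)
                z_soc = z_try + a2 * dz2
                c_soc = constraints(z_soc)
                f_soc = objective(z_soc)
                phi_soc = merit(z_soc, c_soc, f_soc)
                if np.isfinite(phi_soc) and phi_soc <= phi0 \
                        + 1e-4 * alpha * min(ddir, 0.0):
                    z_try, c_try, f_try = z_soc, c_soc, f_soc
                    accepted = True
                    break
            alpha *= 0.5

        if verbose:
            print(f"  it={n_iter:3d} mu={mu:.1e} kkt_mu={kkt_mu:.2e} "
                  f"|c|={np.abs(c).max():.2e} f={f:.6f} "
                  f"amax={alpha_max:.2e} a={alpha:.2e} "
                  f"delta={delta:.1e} acc={accepted}")
        if not accepted:
            if delta < 1e6:
                delta *= 30.0     # retry from the same point, more damped
                continue
            message = "line search failure"
            break
        ratio = alpha / alpha_max
        if ratio >= 0.9:
            delta = max(1e-8, delta / 4.0)
        elif ratio < 0.3:
            delta = min(1e6, delta * 5.0)
        # the cost surface is flat along co-contraction directions: once the
        # iterate is feasible, at the final barrier level, and the objective
        # has stopped moving, declare convergence rather than limit-cycle
        if mu <= max(1e-6, tol) and np.abs(c_try).max(initial=0.0) <= 1e-7 \
                and abs(f_try - f) <= 1e-8 * max(1.0, abs(f)):
            stall += 1
            if stall >= 3:
                z, c, f = z_try, c_try, f_try
                lam = lam_new
                success = True
                message = "converged (objective stall at feasibility)"
                break
        else:
            stall = 0
        step = z_try - z
        gl_old = g + J.T @ lam_new
        z, c, f = z_try, c_try, f_try
        g = gradient(z)
        lam = lam_new
        zL = zL + alpha_dual * dzL
        zU = zU + alpha_dual * dzU
        if np.abs(step).max() > 1e-14:
            pending = (step, gl_old)

    viol = float(np.abs(c).max(initial=0.0))
    return NlpResult(z=z, multipliers=lam, objective=float(f),
                     success=success, n_iter=n_iter, kkt_error=float(kkt),
                     constraint_violation=viol, message=message)
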