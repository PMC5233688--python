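"""Receding-horizon (NMPC) closed loop around the horizon OCP.

Each iteration solves the finite-horizon problem from the measured state,
applies the first fraction (default 5 %) of the optimal excitation signal to
the plant — so the sampling interval is ``delta = fraction * horizon`` —
re-measures the state (noise-free by assumption), shifts the previous
solution by ``delta`` to warm-start the next solve, and repeats until the
hand is within a stop threshold of the target or a time budget runs out.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np

from .arm import forward_kinematics
from .collocation import MeshSpec, OcpProblem, OcpSolution, solve_ocp
from .dynamics import integrate_plant
from .params import ArmParameters, MuscleSet, SystemState

#: receding-horizon subproblems use intervals of roughly this length (s);
#: the horizon mesh is K = clip(round(tph / this), 6, 20)
NMPC_INTERVAL_TARGET = 0.04


def default_nmpc_mesh(horizon: float, degree: int = 3) -> MeshSpec:
    K = int(np.clip(round(horizon / NMPC_INTERVAL_TARGET), 6, 20))
    return MeshSpec(K, degree)


@dataclass
class NmpcConfig:
    """Configuration of the receding-horizon controller.

    ``target`` may be a fixed planar point or a callable ``t -> point``
    (reference trajectory or piecewise-moving target).  For a callable
    target, each horizon uses the target as known at its start time for
    goal-directed (point) targets, and the time-varying reference itself for
    tracking references (``target_is_reference=True``).

    The stop criterion is a hand-error threshold with a simulation time cap;
    ``fixed_duration`` disables the threshold and runs to ``max_time``
    exactly (used to read errors at a fixed instant).
    """

    horizon: float = 0.8
    application_fraction: float = 0.05
    tracking_weight: float = 20.0
    effort_weight: float = 1.0
    target: object = None
    target_is_reference: bool = False
    stop_threshold: float = 0.005
    max_time: float = 3.0
    min_time: float = 0.0
    fixed_duration: bool = False
    mesh: MeshSpec | None = None
    output_grid: float = 0.001
    solver_max_iter_cold: int = 300
    solver_max_iter_warm: int = 60
    solver_tol: float = 1e-7
    solver_method: str = "ip"

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ValueError("prediction horizon must be positive")
        if not 0 < self.application_fraction <= 1:
            raise ValueError("application fraction must be in (0, 1]")
        if not self.stop_threshold > 0:
            raise ValueError("stop threshold must be positive")
        if self.mesh is None:
            self.mesh = default_nmpc_mesh(self.horizon)

    @property
    def delta(self) -> float:
        """Sampling interval: the applied fraction of the horizon (s)."""
        return self.application_fraction * self.horizon

    def horizon_target(self, t0: float):
        """The hand-target function seen by the horizon starting at ``t0``.

        A moving *point* target is frozen at its value currently known
        (evaluated at ``t0``): the controller does not anticipate future
        target jumps.  A tracking *reference* stays time-varying inside the
        horizon.
        """
        if not callable(self.target):
            return np.asarray(self.target, dtype=float)
        if self.target_is_reference:
            return self.target
        return np.asarray(self.target(t0), dtype=float)


@dataclass
class SimulationRecord:
    """Uniform-grid closed-loop time series with solver diagnostics."""

    t: np.ndarray                       # (n,)
    states: np.ndarray                  # (n, 10)
    excitations: np.ndarray             # (n, 6)
    hand: np.ndarray                    # (n, 2)
    speed: np.ndarray                   # (n,)
    diagnostics: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("record times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def state_at(self, time: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.t, time), 0, len(self.t) - 1))
        return self.states[i]

    def hand_at(self, time: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.t, time), 0, len(self.t) - 1))
        return self.hand[i]

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.t}
        names = ["theta1", "theta2", "dtheta1", "dtheta2"] + \
            [f"a{i+1}" for i in range(6)]
        for i, nm in enumerate(names):
            cols[nm] = self.states[:, i]
        for i in range(6):
            cols[f"u{i+1}"] = self.excitations[:, i]
        cols["zeta_x"] = self.hand[:, 0]
        cols["zeta_z"] = self.hand[:, 1]
        cols["speed"] = self.speed
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame) -> "SimulationRecord":
        t = frame["t"].to_numpy()
        names = ["theta1", "theta2", "dtheta1", "dtheta2"] + \
            [f"a{i+1}" for i in range(6)]
        states = frame[names].to_numpy()
        u = frame[[f"u{i+1}" for i in range(6)]].to_numpy()
        hand = frame[["zeta_x", "zeta_z"]].to_numpy()
        speed = frame["speed"].to_numpy()
        return cls(t, states, u, hand, speed)

    @classmethod
    def from_csv(cls, path) -> "SimulationRecord":
        import pandas as pd

        return cls.from_frame(pd.read_csv(path))


class NmpcAbort(RuntimeError):
    """Raised when the horizon OCP fails twice at a closed-loop step; the
    partial record is attached as ``partial_record``."""

    def __init__(self, message: str, partial_record=None):
        super().__init__(message)
        self.partial_record = partial_record


def shift_warm_start(previous: OcpSolution, delta: float) -> OcpSolution:
    """Shift a horizon solution by ``delta`` as the next warm start.

    The shifted guess evaluates the previous interpolants on
    ``[t0 + delta, t0 + tph]`` and holds the final values over the last
    ``delta`` — the standard receding-horizon initial guess.
    """
    if delta < 0:
        raise ValueError("shift must be non-negative")
    t_end = previous.t0 + previous.horizon

    def shifted_times(ts):
        return np.minimum(np.asarray(ts) + delta, t_end)

    times = previous.times
    new_states = previous.interp_x(shifted_times(times))
    node_t = times[1:]
    new_controls = previous.interp_u(shifted_times(node_t))
    return OcpSolution(
        t0=previous.t0, horizon=previous.horizon,
        intervals=previous.intervals, degree=previous.degree,
        times=times.copy(), states=new_states, controls=new_controls,
        objective=np.nan, success=previous.success,
        message="shifted warm start", n_iter=0,
        defect_max=np.nan)


def nmpc_step(current_state: SystemState | np.ndarray,
              warm_start: OcpSolution | None,
              cfg: NmpcConfig, t0: float,
              arm: ArmParameters, muscles: MuscleSet):
    """One receding-horizon iteration.

    Solves the horizon OCP at ``t0`` (warm-started when a previous solution
    is given), applies the first ``delta`` of its control interpolant to the
    plant and returns ``(applied trajectory, new state, solution)``.  A
    failed solve is retried once from a cold start; a second failure raises
    :class:`NmpcAbort`.
    """
    if isinstance(current_state, SystemState):
        current_state = current_state.as_vector()
    spec = OcpProblem(
        t0=t0, horizon=cfg.horizon, x0=current_state,
        tracking_weight=cfg.tracking_weight,
        effort_weight=cfg.effort_weight,
        target=cfg.horizon_target(t0), mesh=cfg.mesh)
    sol = solve_ocp(spec, arm, muscles, initial_guess=warm_start,
                    max_iter=(cfg.solver_max_iter_warm if warm_start
                              is not None else cfg.solver_max_iter_cold),
                    tol=cfg.solver_tol, method=cfg.solver_method)
    if not sol.usable:
        sol = solve_ocp(spec, arm, muscles, initial_guess=None,
                        max_iter=cfg.solver_max_iter_cold, tol=cfg.solver_tol,
                        method=cfg.solver_method)
        if not sol.usable:
            raise NmpcAbort(
                f"horizon OCP failed twice at t = {t0:.3f} s: {sol.message}")
    traj = integrate_plant(current_state, sol.interp_u, cfg.delta,
                           arm, muscles, t0=t0)
    return traj, traj.state(t0 + cfg.delta), sol


def run_nmpc(x0: SystemState | np.ndarray, cfg: NmpcConfig,
             arm: ArmParameters, muscles: MuscleSet) -> SimulationRecord:
    """Run the closed loop until the stop criterion; see :class:`NmpcConfig`.

    The record is sampled on a fixed output grid (default 1 ms) from the
    dense plant trajectories; excitations are sampled from the applied
    control interpolants.
    """
    if isinstance(x0, SystemState):
        x0 = x0.as_vector()
    x0 = np.asarray(x0, dtype=float)
    t_wall = _time.perf_counter()
    segments = []          # (traj, solution) per applied step
    diagnostics = []
    x = x0.copy()
    t0 = 0.0
    sol = None

    def hand_error(x_now, t_now):
        # a tracking reference is judged against its endpoint; a (possibly
        # moving) point target against its currently known value
        if callable(cfg.target):
            tgt = np.asarray(cfg.target(cfg.max_time if
                                        cfg.target_is_reference else t_now),
                             dtype=float)
        else:
            tgt = np.asarray(cfg.target, dtype=float)
        return float(np.linalg.norm(
            forward_kinematics(x_now[0:2], arm) - tgt))

    while True:
        if not cfg.fixed_duration and t0 >= cfg.min_time \
                and hand_error(x, t0) < cfg.stop_threshold:
            break
        if t0 >= cfg.max_time - 1e-12:
            break
        warm = shift_warm_start(sol, cfg.delta) if sol is not None else None
        try:
            traj, x_new, sol = nmpc_step(x, warm, cfg, t0, arm, muscles)
        except NmpcAbort as err:
            err.partial_record = _assemble_record(
                segments, x0, cfg, arm, diagnostics, t_wall)
            raise
        segments.append((traj, sol))
        diagnostics.append({
            "t0": t0, "iterations": sol.n_iter, "success": sol.success,
            "objective": sol.objective, "defect_max": sol.defect_max,
            "message": sol.message})
        x, t0 = x_new, t0 + cfg.delta

    return _assemble_record(segments, x0, cfg, arm, diagnostics, t_wall)


def _assemble_record(segments, x0, cfg, arm, diagnostics,
                     t_wall) -> SimulationRecord:
    dt = cfg.output_grid
    if not segments:
        t = np.array([0.0])
        states = x0[None, :]
        u = np.zeros((1, 6))
    else:
        t_end = segments[-1][0].t_final
        n = int(round(t_end / dt))
        t = np.arange(n + 1) * dt
        states = np.empty((t.size, 10))
        u = np.empty((t.size, 6))
        bounds = [seg.t0 for seg, _ in segments] + [segments[-1][0].t_final]
        idx = np.clip(np.searchsorted(bounds, t, side="right") - 1,
                      0, len(segments) - 1)
        for k, (traj, sol) in enumerate(segments):
            sel = idx == k
            if not np.any(sel):
                continue
            states[sel] = traj.sample(t[sel])
            u[sel] = np.clip(sol.interp_u(t[sel]), 0.0, 1.0)
    hand = forward_kinematics(states[:, 0:2], arm)
    speed = _hand_speed(t, hand)
    meta = {
        "horizon": cfg.horizon, "delta": cfg.delta,
        "tracking_weight": cfg.tracking_weight,
        "effort_weight": cfg.effort_weight,
        "stop_threshold": cfg.stop_threshold,
        "fixed_duration": cfg.fixed_duration,
        "mesh_intervals": cfg.mesh.intervals,
        "mesh_degree": cfg.mesh.degree,
        "wall_time_s": _time.perf_counter() - t_wall,
    }
    return SimulationRecord(t=t, states=states, excitations=u, hand=hand,
                            speed=speed, diagnostics=diagnostics,
                            metadata=meta)


def _hand_speed(t: np.ndarray, hand: np.ndarray) -> np.ndarray:
    if t.size < 2:
        return np.zeros(t.size)
    v = np.gradient(hand, t, axis=0)
    return np.linalg.norm(v, axis=1)
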