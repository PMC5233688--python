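"""The three reaching experiments as reproducible task scenarios.

- ``fixed``: goal-directed reach from the natural initial posture (shoulder
  44 deg, elbow 58 deg, at rest) to a target offset 20 cm to the left of the
  initial hand position, run for each prediction horizon of interest.
- ``tracking``: center-out reaching along a smooth quintic (minimum-jerk)
  straight-line reference to targets spread on a circle around the initial
  hand position.
- ``moving``: goal-directed reach whose target jumps from A to B mid-reach;
  the controller learns of the jump immediately and corrects online.

Each scenario dispatches to the receding-horizon controller (or dynamic
optimization for the fixed task's open-loop baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .arm import forward_kinematics, reachable, UnreachableTargetError
from .dynopt import DoProblem, resimulate, solve_do
from .nmpc import NmpcConfig, run_nmpc
from .params import (ArmParameters, MuscleSet, SystemState,
                     REFERENCE_POSTURE)

DEFAULT_REACH_OFFSET = np.array([-0.20, 0.0])   # "20 cm to the left"
DEFAULT_CIRCLE_RADIUS = 0.20
DEFAULT_SWITCH_TIME = 1.0
DEFAULT_TRACKING_DURATION = 1.5


def min_jerk_reference(start, end, duration: float):
    """Quintic point-to-point hand reference with zero boundary velocity
    and acceleration: s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5.

    Returns a callable ``t -> (2,)`` that holds the endpoints outside
    ``[0, duration]``.
    """
    if not duration > 0:
        raise ValueError("reference duration must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)

    def reference(t):
        tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
        s = tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)
        return start + np.multiply.outer(s, end - start)

    return reference


def min_jerk_profile(tau):
    """The normalized quintic s(tau) itself (vectorized)."""
    tau = np.asarray(tau, dtype=float)
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def build_center_out_targets(radius: float, n: int = 8,
                             center=(0.0, 0.0)) -> np.ndarray:
    """``n`` targets spread evenly on a circle, first at +X from the center.

    Returns an (n, 2) array; point k sits at angle 2*pi*k/n.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if n < 1:
        raise ValueError("need at least one target")
    angles = 2.0 * np.pi * np.arange(n) / n
    center = np.asarray(center, dtype=float)
    return center + radius * np.stack(
        (np.cos(angles), np.sin(angles)), axis=-1)


def moving_target_schedule(point_a, point_b, switch_time: float):
    """Piecewise-constant target: A before ``switch_time``, B from it on."""
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)

    def schedule(t):
        return b if t >= switch_time else a

    return schedule


@dataclass
class TaskSpec:
    """One reaching scenario; see the module docstring for the kinds.

    Geometry fields are interpreted per kind: ``fixed`` uses
    ``target_offset`` from the initial hand position; ``tracking`` uses
    ``circle_radius`` and ``direction_index`` (of ``n_directions``) plus
    ``reference_duration``; ``moving`` uses ``point_a``/``point_b`` offsets
    and ``switch_time``.  ``nmpc`` carries the controller settings; DO runs
    (``use_do=True``, fixed task only) take ``do_final_time``.
    """

    kind: str = "fixed"
    initial_posture: tuple[float, float] = REFERENCE_POSTURE
    target_offset: np.ndarray = field(
        default_factory=lambda: DEFAULT_REACH_OFFSET.copy())
    circle_radius: float = DEFAULT_CIRCLE_RADIUS
    n_directions: int = 8
    direction_index: int = 0
    reference_duration: float = DEFAULT_TRACKING_DURATION
    point_a: np.ndarray | None = None
    point_b: np.ndarray | None = None
    switch_time: float = DEFAULT_SWITCH_TIME
    nmpc: NmpcConfig = field(default_factory=lambda: NmpcConfig(horizon=0.8))
    use_do: bool = False
    do_final_time: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "tracking", "moving"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "moving" and self.use_do:
            raise ValueError("a moving target cannot be simulated open loop "
                             "with a fixed terminal state")

    def initial_state(self) -> SystemState:
        return SystemState(*self.initial_posture)

    def initial_hand(self, arm: ArmParameters) -> np.ndarray:
        return forward_kinematics(np.asarray(self.initial_posture), arm)

    def resolve_targets(self, arm: ArmParameters):
        """Final target point(s) of the scenario in the shoulder frame."""
        zeta0 = self.initial_hand(arm)
        if self.kind == "fixed":
            return zeta0 + np.asarray(self.target_offset, dtype=float)
        if self.kind == "tracking":
            ring = build_center_out_targets(
                self.circle_radius, self.n_directions, zeta0)
            return ring[self.direction_index % self.n_directions]
        a = zeta0 + (np.asarray(self.point_a, dtype=float)
                     if self.point_a is not None else DEFAULT_REACH_OFFSET)
        b = a + (np.asarray(self.point_b, dtype=float)
                 if self.point_b is not None else np.array([0.0, -0.10]))
        return a, b

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "kind": self.kind,
            "initial_posture_deg": [math.degrees(v)
                                    for v in self.initial_posture],
            "nmpc": {"horizon_s": self.nmpc.horizon,
                     "application_fraction": self.nmpc.application_fraction,
                     "tracking_weight": self.nmpc.tracking_weight,
                     "effort_weight": self.nmpc.effort_weight,
                     "stop_threshold_m": self.nmpc.stop_threshold,
                     "max_time_s": self.nmpc.max_time,
                     "fixed_duration": self.nmpc.fixed_duration},
            "use_do": self.use_do,
            "do_final_time_s": self.do_final_time,
        }
        if self.kind == "fixed":
            doc["target_offset_m"] = list(map(float, self.target_offset))
        elif self.kind == "tracking":
            doc.update(circle_radius_m=self.circle_radius,
                       n_directions=self.n_directions,
                       direction_index=self.direction_index,
                       reference_duration_s=self.reference_duration)
        else:
            doc.update(
                point_a_offset_m=None if self.point_a is None
                else list(map(float, self.point_a)),
                point_b_offset_m=None if self.point_b is None
                else list(map(float, self.point_b)),
                switch_time_s=self.switch_time)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TaskSpec":
        doc = yaml.safe_load(Path(path).read_text())
        nm = doc.get("nmpc", {})
        cfg = NmpcConfig(
            horizon=nm.get("horizon_s", 0.8),
            application_fraction=nm.get("application_fraction", 0.05),
            tracking_weight=nm.get("tracking_weight", 20.0),
            effort_weight=nm.get("effort_weight", 1.0),
            stop_threshold=nm.get("stop_threshold_m", 0.005),
            max_time=nm.get("max_time_s", 3.0),
            fixed_duration=nm.get("fixed_duration", False))
        kw = dict(kind=doc["kind"], nmpc=cfg,
                  use_do=doc.get("use_do", False),
                  do_final_time=doc.get("do_final_time_s", 1.5))
        if "initial_posture_deg" in doc:
            kw["initial_posture"] = tuple(
                math.radians(v) for v in doc["initial_posture_deg"])
        if doc["kind"] == "fixed" and "target_offset_m" in doc:
            kw["target_offset"] = np.asarray(doc["target_offset_m"])
        if doc["kind"] == "tracking":
            kw.update(circle_radius=doc.get("circle_radius_m", 0.2),
                      n_directions=doc.get("n_directions", 8),
                      direction_index=doc.get("direction_index", 0),
                      reference_duration=doc.get("reference_duration_s", 1.5))
        if doc["kind"] == "moving":
            if doc.get("point_a_offset_m") is not None:
                kw["point_a"] = np.asarray(doc["point_a_offset_m"])
            if doc.get("point_b_offset_m") is not None:
                kw["point_b"] = np.asarray(doc["point_b_offset_m"])
            kw["switch_time"] = doc.get("switch_time_s", 1.0)
        return cls(**kw)


def _require_reachable(point, arm: ArmParameters, label: str) -> None:
    if not reachable(point, arm):
        raise UnreachableTargetError(
            f"{label} at {np.round(point, 4)} lies outside the reachable "
            f"annulus of the arm")


def run_task(spec: TaskSpec, arm: ArmParameters, muscles: MuscleSet):
    """Run a scenario; returns a :class:`SimulationRecord` (and the
    :class:`OcpSolution` as well for DO variants)."""
    x0 = spec.initial_state()
    zeta0 = spec.initial_hand(arm)

    if spec.kind == "fixed":
        target = spec.resolve_targets(arm)
        _require_reachable(target, arm, "reach target")
        if spec.use_do:
            problem = DoProblem(final_time=spec.do_final_time,
                                x0=x0.as_vector(), target=target)
            sol = solve_do(problem, arm, muscles)
            rec = resimulate(sol, x0, arm, muscles)
            rec.metadata.update(task="fixed", target=target.tolist())
            return rec, sol
        cfg = replace(spec.nmpc, target=target, target_is_reference=False)
        rec = run_nmpc(x0, cfg, arm, muscles)
        rec.metadata.update(task="fixed", target=target.tolist())
        return rec

    if spec.kind == "tracking":
        target = spec.resolve_targets(arm)
        _require_reachable(target, arm, "center-out target")
        ref = min_jerk_reference(zeta0, target, spec.reference_duration)
        cfg = replace(spec.nmpc, target=ref, target_is_reference=True,
                      min_time=spec.reference_duration)
        rec = run_nmpc(x0, cfg, arm, muscles)
        rec.metadata.update(task="tracking", target=target.tolist(),
                            reference_duration=spec.reference_duration)
        return rec

    # moving target
    a, b = spec.resolve_targets(arm)
    _require_reachable(a, arm, "target A")
    _require_reachable(b, arm, "target B")
    if not 0.0 < spec.switch_time < spec.nmpc.max_time:
        raise ValueError("switch time must fall inside the simulation")
    schedule = moving_target_schedule(a, b, spec.switch_time)
    cfg = replace(spec.nmpc, target=schedule, target_is_reference=False,
                  min_time=spec.switch_time)
    rec = run_nmpc(x0, cfg, arm, muscles)
    rec.metadata.update(task="moving", target_a=a.tolist(),
                        target_b=b.tolist(), switch_time=spec.switch_time)
    return rec


def horizon_sweep(horizons, arm: ArmParameters, muscles: MuscleSet,
                  read_time: float = 1.5):
    """Run the fixed-target task for several prediction horizons.

    Returns a list of dicts with the reaching error at ``read_time`` (% of
    the 20 cm reach distance), peak hand speed and its time — the summary
    of the horizon-length experiment.
    """
    from .analysis import reaching_error, speed_profile

    rows = []
    for tph in horizons:
        spec = TaskSpec(kind="fixed",
                        nmpc=NmpcConfig(horizon=tph, fixed_duration=True,
                                        max_time=read_time))
        rec = run_task(spec, arm, muscles)
        target = np.asarray(rec.metadata["target"])
        prof = speed_profile(rec)
        rows.append({
            "horizon": tph,
            "error_percent": reaching_error(rec, target, read_time),
            "peak_speed": prof.peak_value,
            "time_of_peak": prof.peak_time,
            "record": rec,
        })
    return rows
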