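"""Model parameter containers and configuration loading.

The arm is a planar two-segment linkage (upper arm, forearm) moving in a
horizontal plane at shoulder height, actuated by six lumped muscle groups:
mono-articular shoulder flexor/extensor (muscles 1, 2), mono-articular elbow
flexor/extensor (muscles 3, 4) and bi-articular flexor/extensor (muscles 5, 6).

All quantities are stored internally in SI units (m, kg, s, N, rad).  The
bundled configuration file ``data/default_model.yaml`` mirrors the published
parameter tables in their printed units (mm, kg·cm², deg) with explicit unit
suffixes in the keys; :func:`load_model` performs the conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

GROUND, UPPER_ARM, FOREARM = 0, 1, 2

_SEGMENT_IDS = {"ground": GROUND, "upper_arm": UPPER_ARM, "forearm": FOREARM}

#: reference posture (rad) at which optional muscle calibration is performed:
#: the "natural" initial arm position, shoulder 44 deg / elbow 58 deg.
REFERENCE_POSTURE = (math.radians(44.0), math.radians(58.0))


@dataclass(frozen=True)
class ArmParameters:
    """Inertial and geometric parameters of the two-segment planar arm.

    Inertias are about each segment's centre of mass, about the axis
    perpendicular to the plane of motion.  CoM offsets are measured from the
    proximal joint along the segment.  ``joint_damping`` is an optional
    viscous coefficient (N·m·s/rad) applied equally at both joints.
    """

    upper_arm_mass: float = 1.93
    forearm_mass: float = 1.52
    upper_arm_inertia: float = 141e-4
    forearm_inertia: float = 188e-4
    upper_arm_length: float = 0.290
    forearm_length: float = 0.300
    upper_arm_com: float = 0.145
    forearm_com: float = 0.150
    joint_damping: float = 0.0

    def __post_init__(self) -> None:
        for name in ("upper_arm_mass", "forearm_mass", "upper_arm_inertia",
                     "forearm_inertia", "upper_arm_length", "forearm_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.upper_arm_com <= self.upper_arm_length:
            raise ValueError("upper_arm_com must lie in (0, upper_arm_length]")
        if not 0 < self.forearm_com <= self.forearm_length:
            raise ValueError("forearm_com must lie in (0, forearm_length]")
        if self.joint_damping < 0:
            raise ValueError("joint_damping must be non-negative")


@dataclass(frozen=True)
class Muscle:
    """A single Hill-type muscle group with straight-line attachment geometry.

    ``origin`` / ``insertion`` are planar points expressed in the frame of the
    segment they attach to (x along the segment toward the distal joint).
    ``optimal_fiber_length`` may be ``None``, in which case it is calibrated so
    the fibre sits at its optimal length at the reference posture (see
    :meth:`MuscleSet.calibrated`).
    """

    name: str
    max_isometric_force: float
    tendon_slack_length: float
    pennation_angle: float
    origin_segment: int
    origin_point: tuple[float, float]
    insertion_segment: int
    insertion_point: tuple[float, float]
    optimal_fiber_length: float | None = None
    activation_time_constant: float = 0.010
    deactivation_time_constant: float = 0.040

    def __post_init__(self) -> None:
        if not self.max_isometric_force > 0:
            raise ValueError(f"{self.name}: max_isometric_force must be > 0")
        if self.tendon_slack_length < 0:
            raise ValueError(f"{self.name}: tendon_slack_length must be >= 0")
        if not 0 <= self.pennation_angle < math.pi / 2:
            raise ValueError(f"{self.name}: pennation_angle must be in [0, pi/2)")
        if not (self.activation_time_constant > 0
                and self.deactivation_time_constant > 0):
            raise ValueError(f"{self.name}: time constants must be > 0")
        if self.activation_time_constant > self.deactivation_time_constant:
            raise ValueError(f"{self.name}: activation time constant must not "
                             "exceed the deactivation time constant")
        if self.optimal_fiber_length is not None and self.optimal_fiber_length <= 0:
            raise ValueError(f"{self.name}: optimal_fiber_length must be > 0")
        for seg in (self.origin_segment, self.insertion_segment):
            if seg not in (GROUND, UPPER_ARM, FOREARM):
                raise ValueError(f"{self.name}: unknown segment id {seg}")
        if self.origin_segment == self.insertion_segment:
            raise ValueError(f"{self.name}: origin and insertion on one segment")


class MuscleSet:
    """The six-muscle actuation set, with parameters pre-packed into arrays.

    Array attributes (all length 6, muscle order 1..6):

    - ``f0max`` — maximum isometric forces (N)
    - ``tendon_slack`` — tendon slack lengths (m)
    - ``cos_pennation`` — cosine of the pennation angles
    - ``optimal_fiber`` — optimal fibre lengths (m); requires calibration
    - ``tau_act`` / ``tau_deact`` — activation dynamics time constants (s)
    """

    def __init__(self, muscles: Sequence[Muscle]):
        if len(muscles) != 6:
            raise ValueError("MuscleSet requires exactly six muscles")
        self.muscles = tuple(muscles)
        self.f0max = np.array([m.max_isometric_force for m in muscles])
        self.tendon_slack = np.array([m.tendon_slack_length for m in muscles])
        self.pennation = np.array([m.pennation_angle for m in muscles])
        self.cos_pennation = np.cos(self.pennation)
        self.tau_act = np.array([m.activation_time_constant for m in muscles])
        self.tau_deact = np.array([m.deactivation_time_constant for m in muscles])
        self.origin_segment = np.array([m.origin_segment for m in muscles])
        self.origin_xy = np.array([m.origin_point for m in muscles])
        self.insertion_segment = np.array([m.insertion_segment for m in muscles])
        self.insertion_xy = np.array([m.insertion_point for m in muscles])
        opt = [m.optimal_fiber_length for m in muscles]
        self._calibrated = all(v is not None for v in opt)
        self.optimal_fiber = (np.array([float(v) for v in opt])
                              if self._calibrated else None)

    def __iter__(self):
        return iter(self.muscles)

    def __len__(self) -> int:
        return 6

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    @property
    def is_calibrated(self) -> bool:
        return self._calibrated

    def calibrated(self, arm: ArmParameters,
                   posture: tuple[float, float] = REFERENCE_POSTURE) -> "MuscleSet":
        """Return a copy with any missing optimal fibre lengths filled in.

        Missing values are set so that the fibre is exactly at optimal length
        (normalized length 1) at the given posture: ``l_opt = (L_MT(posture) -
        L_SE) / cos(alpha_p)``.  Muscles with explicit optimal fibre lengths
        are left untouched.
        """
        from .muscles import musculotendon_geometry  # local: avoid cycle

        lengths, _ = musculotendon_geometry(posture[0], posture[1], arm, self)
        fixed = []
        for m, lmt in zip(self.muscles, lengths):
            if m.optimal_fiber_length is None:
                lopt = (lmt - m.tendon_slack_length) / math.cos(m.pennation_angle)
                if lopt <= 0:
                    raise ValueError(
                        f"{m.name}: musculotendon path ({lmt:.4f} m) shorter "
                        f"than tendon slack at the calibration posture")
                m = replace(m, optimal_fiber_length=float(lopt))
            fixed.append(m)
        return MuscleSet(fixed)


@dataclass
class SystemState:
    """The 10-dimensional plant state.

    Flattening order is fixed: (theta1, theta2, theta1_dot, theta2_dot,
    a1..a6).  Angles in rad, velocities in rad/s, activations dimensionless
    in [0, 1].
    """

    shoulder_angle: float
    elbow_angle: float
    shoulder_velocity: float = 0.0
    elbow_velocity: float = 0.0
    activations: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float)
        if self.activations.shape != (6,):
            raise ValueError("activations must be a 6-vector")
        if not np.all(np.isfinite(self.as_vector())):
            raise ValueError("state components must be finite")
        if np.any(self.activations < -1e-12) or np.any(self.activations > 1 + 1e-12):
            raise ValueError("activations must lie in [0, 1]")
        np.clip(self.activations, 0.0, 1.0, out=self.activations)

    def as_vector(self) -> np.ndarray:
        return np.concatenate((
            [self.shoulder_angle, self.elbow_angle,
             self.shoulder_velocity, self.elbow_velocity],
            self.activations))

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "SystemState":
        x = np.asarray(x, dtype=float)
        if x.shape != (10,):
            raise ValueError("state vector must have length 10")
        return cls(x[0], x[1], x[2], x[3], x[4:10].copy())

    @property
    def joint_angles(self) -> np.ndarray:
        return np.array([self.shoulder_angle, self.elbow_angle])

    @property
    def joint_velocities(self) -> np.ndarray:
        return np.array([self.shoulder_velocity, self.elbow_velocity])


def check_excitations(u: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate a neural excitation vector (6 components in [0, 1]).

    Excitations are the control inputs: the fraction of a muscle's motor-unit
    pool that is recruited.  Returns the array clipped to the unit box.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (6,):
        raise ValueError("excitation vector must have 6 components")
    if not np.all(np.isfinite(u)):
        raise ValueError("excitations must be finite")
    if np.any(u < -tol) or np.any(u > 1 + tol):
        raise ValueError("excitations must lie in [0, 1]")
    return np.clip(u, 0.0, 1.0)


@dataclass(frozen=True)
class ExcitationVector:
    """Validated 6-vector of neural excitations, each in [0, 1]."""

    u: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "u", check_excitations(self.u))


# ---------------------------------------------------------------------------
# configuration loading


def _length(entry: dict, key: str) -> float:
    if f"{key}_mm" in entry:
        return float(entry[f"{key}_mm"]) * 1e-3
    return float(entry[f"{key}_m"])


def _load_arm(cfg: dict) -> ArmParameters:
    seg = cfg["segments"]
    ua, fa = seg["upper_arm"], seg["forearm"]

    def inertia(e: dict) -> float:
        if "inertia_kg_cm2" in e:
            return float(e["inertia_kg_cm2"]) * 1e-4
        return float(e["inertia_kg_m2"])

    return ArmParameters(
        upper_arm_mass=float(ua["mass_kg"]),
        forearm_mass=float(fa["mass_kg"]),
        upper_arm_inertia=inertia(ua),
        forearm_inertia=inertia(fa),
        upper_arm_length=_length(ua, "length"),
        forearm_length=_length(fa, "length"),
        upper_arm_com=_length(ua, "com"),
        forearm_com=_length(fa, "com"),
        joint_damping=float(cfg.get("joint_damping_Nms_per_rad", 0.0)),
    )


def _load_muscle(entry: dict) -> Muscle:
    def point(e: dict) -> tuple[int, tuple[float, float]]:
        seg = _SEGMENT_IDS[e["segment"]]
        xy = e["xy_m"]
        return seg, (float(xy[0]), float(xy[1]))

    o_seg, o_xy = point(entry["origin"])
    i_seg, i_xy = point(entry["insertion"])
    opt = entry.get("optimal_fiber_mm")
    return Muscle(
        name=entry["name"],
        max_isometric_force=float(entry["f0max_N"]),
        tendon_slack_length=float(entry["tendon_slack_mm"]) * 1e-3,
        pennation_angle=math.radians(float(entry["pennation_deg"])),
        origin_segment=o_seg, origin_point=o_xy,
        insertion_segment=i_seg, insertion_point=i_xy,
        optimal_fiber_length=None if opt is None else float(opt) * 1e-3,
        activation_time_constant=float(entry.get("activation_tau_s", 0.010)),
        deactivation_time_constant=float(entry.get("deactivation_tau_s", 0.040)),
    )


def load_model(path: str | Path | None = None,
               calibrate: bool = True) -> tuple[ArmParameters, MuscleSet]:
    """Load arm and muscle parameters from a YAML model file.

    With ``path=None`` the bundled default model is loaded.  When
    ``calibrate`` is true (default), muscles whose optimal fibre length is
    unspecified are calibrated at the reference posture.
    """
    if path is None:
        text = (resources.files("reachmpc") / "data/default_model.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    arm = _load_arm(cfg["arm"])
    muscles = MuscleSet([_load_muscle(e) for e in cfg["muscles"]])
    if calibrate and not muscles.is_calibrated:
        muscles = muscles.calibrated(arm)
    return arm, muscles


def default_model() -> tuple[ArmParameters, MuscleSet]:
    """The bundled default arm + muscle model, calibrated and ready to use."""
    return load_model(None)
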