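"""Rigid-body pose math and needle-guidance parameters.

Two electromagnetically tracked 6-DOF sensors — one at the tip of the
tracheostomy (PDT) needle, one advanced through the bronchoscope working
channel into the trachea as the target — report position (mm) and
orientation (roll/pitch/yaw, degrees) in the transmitter's Cartesian
frame.  From the two poses this module computes the three guidance
parameters shown to the operator:

* ``R``   — radial distance to target: the perpendicular (lateral)
  distance of the target from the needle's axis line.  It predicts
  whether continued insertion along the current trajectory will hit
  the target.
* ``DTT`` — depth to target: the signed component of (target − tip)
  along the needle axis; positive while the target lies ahead of the
  tip, negative once overshot.
* ``α``   — angular deviation of the needle axis from the ideal
  anterior–posterior insertion direction (the coronal-plane normal,
  anatomical +Z), folded into [0°, 90°].

Units are fixed package-wide: millimetres, degrees, seconds.

Axis conventions (right-handed): +Z anterior (coronal-plane normal),
+Y cranial, +X patient-left.  Euler angles compose intrinsically as
Z-Y-X (yaw, then pitch, then roll); the needle shaft direction is the
sensor's local +Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import FrameMismatchError

__all__ = [
    "Frame",
    "Pose6DOF",
    "GuidanceParameters",
    "RigidTransform",
    "TRANSMITTER_FRAME",
    "ANATOMICAL_FRAME",
    "NEEDLE_LOCAL_AXIS",
    "euler_to_rotation",
    "rotation_to_euler",
    "needle_axis",
    "axis_to_euler",
    "guidance_parameters",
    "apply_transform",
    "normalize_angle_deg",
]

#: Local shaft direction of the needle sensor (secured at the needle tip,
#: aligned with the cannula).
NEEDLE_LOCAL_AXIS = np.array([0.0, 0.0, 1.0])

_AXIS_CONVENTION = (
    "right-handed; +Z = anterior (coronal-plane normal); +Y = cranial; "
    "+X = patient-left"
)


def normalize_angle_deg(angle: float) -> float:
    """Normalize an angle in degrees to the interval (−180°, 180°]."""
    r = float(angle) % 360.0
    if r > 180.0:
        r -= 360.0
    return r


@dataclass(frozen=True)
class Frame:
    """A named Cartesian coordinate frame (orthonormal, right-handed)."""

    name: str
    origin_description: str = ""
    axis_convention: str = _AXIS_CONVENTION


#: Frame of the electromagnetic transmitter (raw tracker output).
TRANSMITTER_FRAME = Frame(
    "transmitter", "origin at the electromagnetic field transmitter"
)

#: Patient-anatomical frame; +Z is the ideal needle insertion direction.
ANATOMICAL_FRAME = Frame(
    "anatomical", "origin at the nominal skin entry point, axes anatomical"
)


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite angle or coordinate: {v!r}")


def euler_to_rotation(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Rotation matrix from roll/pitch/yaw in degrees.

    Composition is intrinsic Z-Y-X: first yaw about +Z, then pitch about
    the new +Y, then roll about the new +X — i.e.
    ``Rz(yaw) @ Ry(pitch) @ Rx(roll)``.

    Returns a 3×3 orthonormal matrix with determinant +1.
    """
    _check_finite(roll, pitch, yaw)
    return Rotation.from_euler("ZYX", [yaw, pitch, roll], degrees=True).as_matrix()


def rotation_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_rotation`: (roll, pitch, yaw) degrees."""
    yaw, pitch, roll = Rotation.from_matrix(matrix).as_euler("ZYX", degrees=True)
    return float(roll), float(pitch), float(yaw)


@dataclass(frozen=True)
class Pose6DOF:
    """One sensor's position and orientation at an instant.

    Angles are normalized to (−180°, 180°] on construction.
    """

    position: np.ndarray
    roll: float
    pitch: float
    yaw: float
    frame: Frame = TRANSMITTER_FRAME
    timestamp: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite position")
        _check_finite(self.roll, self.pitch, self.yaw)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "roll", normalize_angle_deg(self.roll))
        object.__setattr__(self, "pitch", normalize_angle_deg(self.pitch))
        object.__setattr__(self, "yaw", normalize_angle_deg(self.yaw))

    def rotation(self) -> np.ndarray:
        """3×3 rotation matrix of this orientation."""
        return euler_to_rotation(self.roll, self.pitch, self.yaw)


def needle_axis(pose: Pose6DOF) -> np.ndarray:
    """Unit vector of the needle shaft direction (sensor local +Z) in the
    pose's frame."""
    axis = pose.rotation() @ NEEDLE_LOCAL_AXIS
    return axis / np.linalg.norm(axis)


def axis_to_euler(axis: np.ndarray) -> tuple[float, float, float]:
    """Roll/pitch/yaw (degrees, roll = 0) whose rotation maps local +Z onto
    ``axis``.  Used by the simulator to emit poses from a heading vector."""
    v = np.asarray(axis, dtype=float)
    v = v / np.linalg.norm(v)
    pitch = math.degrees(math.acos(max(-1.0, min(1.0, v[2]))))
    yaw = math.degrees(math.atan2(v[1], v[0])) if (v[0] ** 2 + v[1] ** 2) > 0 else 0.0
    return 0.0, pitch, yaw


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform (rotation then translation), mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tra.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(rot)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation determinant is not +1 (improper transform)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def random(cls, rng: np.random.Generator) -> "RigidTransform":
        """Uniform random rotation with a translation ~ N(0, 50 mm)."""
        rot = Rotation.random(random_state=rng).as_matrix()
        return cls(rot, rng.normal(0.0, 50.0, size=3))

    def apply_point(self, point: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(point, dtype=float) + self.translation

    def apply_pose(self, pose: Pose6DOF) -> Pose6DOF:
        new_rot = self.rotation @ pose.rotation()
        roll, pitch, yaw = rotation_to_euler(new_rot)
        return Pose6DOF(
            self.apply_point(pose.position),
            roll,
            pitch,
            yaw,
            frame=pose.frame,
            timestamp=pose.timestamp,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def apply_transform(
    obj: Union[Pose6DOF, np.ndarray], transform: RigidTransform
) -> Union[Pose6DOF, np.ndarray]:
    """Apply a rigid transform to a pose or a bare point; returns the same kind."""
    if isinstance(obj, Pose6DOF):
        return transform.apply_pose(obj)
    return transform.apply_point(obj)


@dataclass(frozen=True)
class GuidanceParameters:
    """The three on-screen guidance parameters plus the Euclidean distance.

    ``radial_distance_R`` is the live-guidance lateral miss distance;
    ``euclidean_distance`` is the straight-line tip-to-target distance used
    as the completion ("radius from target") outcome metric.
    ``alpha_transverse_deg`` is an optional signed variant of α projected
    into the transverse plane (positive toward patient-left), matching the
    clock-face reading of the safe entry window; it is reported but not used
    by the default feedback rules.
    """

    radial_distance_R: float
    alpha_deg: float
    depth_to_target_DTT: float
    euclidean_distance: float
    alpha_transverse_deg: float = 0.0

    def __post_init__(self):
        if self.radial_distance_R < 0 or self.euclidean_distance < 0:
            raise ValueError("distances must be non-negative")
        if not (0.0 <= self.alpha_deg <= 90.0):
            raise ValueError("alpha_deg must lie in [0, 90]")


def guidance_parameters(
    needle: Pose6DOF,
    target_position: Union[np.ndarray, Pose6DOF],
    anatomical: RigidTransform | None = None,
) -> GuidanceParameters:
    """Compute R, α, DTT and the Euclidean distance from a needle pose and a
    target position.

    ``anatomical`` registers the tracking (transmitter) frame to the
    anatomical frame whose +Z is the ideal insertion direction; identity by
    default (transmitter frame taken as anatomical).  If ``target_position``
    is itself a pose it must share the needle's frame unless a registration
    transform is supplied.
    """
    if isinstance(target_position, Pose6DOF):
        if target_position.frame != needle.frame and anatomical is None:
            raise FrameMismatchError(
                f"needle in frame {needle.frame.name!r} but target in frame "
                f"{target_position.frame.name!r} with no registration transform"
            )
        target = target_position.position
    else:
        target = np.asarray(target_position, dtype=float)

    t = anatomical if anatomical is not None else RigidTransform.identity()
    tip = t.apply_point(needle.position)
    tgt = t.apply_point(target)
    axis = t.rotation @ needle_axis(needle)
    axis_norm = np.linalg.norm(axis)
    if not axis_norm > 0.5:  # needle_axis returns a unit vector; guard anyway
        raise RuntimeError("internal invariant violation: zero-length needle axis")
    axis = axis / axis_norm

    d = tgt - tip
    dtt = float(d @ axis)
    radial = float(np.linalg.norm(d - dtt * axis))
    euclid = float(np.linalg.norm(d))

    cos_a = float(np.clip(axis @ np.array([0.0, 0.0, 1.0]), -1.0, 1.0))
    alpha_3d = math.degrees(math.acos(cos_a))  # cone angle in [0, 180]
    alpha = min(alpha_3d, 180.0 - alpha_3d)  # fold to deviation in [0, 90]
    alpha_transverse = math.degrees(math.atan2(axis[0], axis[2]))

    return GuidanceParameters(
        radial_distance_R=radial,
        alpha_deg=alpha,
        depth_to_target_DTT=dtt,
        euclidean_distance=euclid,
        alpha_transverse_deg=alpha_transverse,
    )
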