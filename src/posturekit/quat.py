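"""Quaternion algebra and Euler-angle conversion.

Conventions (fixed for the whole package):

* Hamilton product, right-handed, ``ijk = -1``, scalar-first layout
  ``(q0, q1, q2, q3)``.
* Unit quaternions are canonicalized to ``q0 >= 0`` at construction; ``q`` and
  ``-q`` encode the same rotation.
* Euler angles follow the aerospace ZYX (yaw-pitch-roll) sequence: the rotation
  matrix is ``Rz(yaw) @ Ry(pitch) @ Rx(roll)``, mapping body/sensor vectors
  into the global frame.
* The global frame is north-east-down: x north, y east, z toward the ground.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Quaternion", "EulerAngles"]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class EulerAngles:
    """ZYX Euler angles in radians: roll about x, pitch about y, yaw about z."""

    roll: float
    pitch: float
    yaw: float

    def __post_init__(self):
        if not (-math.pi / 2 - 1e-12 <= self.pitch <= math.pi / 2 + 1e-12):
            raise ValueError(f"pitch {self.pitch} outside [-pi/2, pi/2]")


class Quaternion:
    """Unit quaternion ``q0 + q1 i + q2 j + q3 k``, canonical sign ``q0 >= 0``."""

    __slots__ = ("_q",)

    def __init__(self, q0: float, q1: float, q2: float, q3: float):
        q = np.array([q0, q1, q2, q3], dtype=float)
        n = np.linalg.norm(q)
        if n == 0.0:
            raise ZeroDivisionError("zero quaternion has no direction")
        q /= n
        if q[0] < 0.0:
            q = -q
        object.__setattr__(self, "_q", q)

    # -- constructors -------------------------------------------------

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, q) -> "Quaternion":
        q = np.asarray(q, dtype=float)
        return cls(q[0], q[1], q[2], q[3])

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float) -> "Quaternion":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0.0:
            raise ZeroDivisionError("zero rotation axis")
        half = 0.5 * angle_rad
        return cls(math.cos(half), *(math.sin(half) * axis / n))

    @classmethod
    def from_euler(cls, e: EulerAngles) -> "Quaternion":
        """ZYX half-angle product: quaternion of ``Rz(yaw) Ry(pitch) Rx(roll)``."""
        cr, sr = math.cos(e.roll / 2), math.sin(e.roll / 2)
        cp, sp = math.cos(e.pitch / 2), math.sin(e.pitch / 2)
        cy, sy = math.cos(e.yaw / 2), math.sin(e.yaw / 2)
        return cls(
            cr * cp * cy + sr * sp * sy,
            sr * cp * cy - cr * sp * sy,
            cr * sp * cy + sr * cp * sy,
            cr * cp * sy - sr * sp * cy,
        )

    # -- accessors ----------------------------------------------------

    @property
    def q0(self) -> float:
        return float(self._q[0])

    @property
    def vector(self) -> np.ndarray:
        return self._q[1:].copy()

    def as_array(self) -> np.ndarray:
        return self._q.copy()

    def __iter__(self):
        return iter(self._q)

    def __repr__(self):
        return "Quaternion({:.9g}, {:.9g}, {:.9g}, {:.9g})".format(*self._q)

    # -- algebra ------------------------------------------------------

    def multiply(self, other: "Quaternion") -> "Quaternion":
        """Hamilton product ``self ⊗ other`` (apply ``other`` first)."""
        return Quaternion.from_array(_qmult(self._q, other._q))

    __matmul__ = multiply

    def conjugate(self) -> "Quaternion":
        w, x, y, z = self._q
        return Quaternion(w, -x, -y, -z)

    def rotate_vector(self, v) -> np.ndarray:
        """Sandwich product ``q ⊗ (0, v) ⊗ q*``: rotate v from the local into
        the global frame."""
        return _rotate(self._q, np.asarray(v, dtype=float))

    def to_rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self._q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def to_euler(self) -> EulerAngles:
        """ZYX Euler decomposition; at gimbal lock (|pitch| = 90°) roll := 0."""
        w, x, y, z = self._q
        s = 2 * (w * y - z * x)
        if abs(s) >= 1.0 - 1e-12:
            pitch = math.copysign(math.pi / 2, s)
            # roll and yaw share one degree of freedom; pin roll = 0, then
            # q = qz(yaw) ⊗ qy(±pi/2) gives tan(yaw/2) = -sign(pitch)·q1/q0
            yaw = 2.0 * math.atan2(-math.copysign(1.0, s) * x, w)
            return EulerAngles(0.0, pitch, _wrap_pi(yaw))
        roll = math.atan2(2 * (w * x + y * z), 1 - 2 * (x * x + y * y))
        pitch = math.asin(max(-1.0, min(1.0, s)))
        yaw = math.atan2(2 * (w * z + x * y), 1 - 2 * (y * y + z * z))
        return EulerAngles(roll, pitch, yaw)

    def angle_to(self, other: "Quaternion") -> float:
        """Geodesic rotation angle between the two rotations, radians.

        Uses the chord form ‖Δq‖ = 2 sin(θ/4), which keeps full precision for
        tiny angles where acos of the dot product would floor out near 1e-8.
        """
        d = min(float(np.linalg.norm(self._q - other._q)),
                float(np.linalg.norm(self._q + other._q)))
        return 4.0 * math.asin(min(1.0, 0.5 * d))

    def __eq__(self, other):
        if not isinstance(other, Quaternion):
            return NotImplemented
        return bool(np.allclose(self._q, other._q, atol=_NORM_TOL))

    def __hash__(self):
        return hash(tuple(np.round(self._q, 9)))


# ---------------------------------------------------------------------------
# Array-level kernels.  The fusion filter integrates tens of thousands of
# frames; these avoid object construction in the hot loop.

def _qmult(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def _qconj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def _rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """q ⊗ (0,v) ⊗ q* without building the pure quaternion explicitly."""
    w, x, y, z = q
    qv = np.array([x, y, z])
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def _rotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """q* ⊗ (0,v) ⊗ q: rotate v from the global into the local frame."""
    return _rotate(_qconj(q), v)


def _normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi
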