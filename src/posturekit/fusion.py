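"""Initial attitude and gradient-descent MARG orientation fusion.

The static attitude comes from gravity and the magnetic field: roll and pitch
from the accelerometer (which reads the gravity direction ``(0,0,1)`` g in the
north-east-down global frame when still), yaw from the tilt-compensated
horizontal field.  During motion, the filter integrates the gyroscope
quaternion rate and corrects it each frame with the normalized gradient of a
two-part objective — align the measured accelerometer with gravity and the
measured magnetometer with the earth field flattened to the x-z plane — the
complementary structure of Madgwick's gradient-descent MARG filter.

The sensor is strapped to a limb at an unknown fixed offset; ``sensor_to_body``
captures that offset during the north-facing neutral stance (body frame ==
global frame), after which per-frame body orientations follow from
``qBG(t) = qSG(t) ⊗ qSB*``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional

import numpy as np

from posturekit.errors import NonMonotoneTime, NotStatic, StillIntervalTooShort, ZeroVector
from posturekit.quat import (
    EulerAngles,
    Quaternion,
    _normalize,
    _qconj,
    _qmult,
    _rotate,
    _rotate_inv,
)

__all__ = [
    "ImuTrace",
    "OrientationTrack",
    "initial_euler",
    "initial_quaternion",
    "objective_error",
    "gradient_step",
    "fuse_trace",
    "sensor_to_body",
]

DEG = math.pi / 180.0


@dataclass(frozen=True)
class ImuTrace:
    """One node's timestamped 9-axis stream.

    accel in g, gyro in deg/s, mag in gauss (calibrated unless stated
    otherwise); timestamps in seconds, strictly increasing.
    """

    node_id: str
    rate: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray

    def __post_init__(self):
        for name in ("t", "accel", "gyro", "mag"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        n = len(self.t)
        if not (self.accel.shape == self.gyro.shape == self.mag.shape == (n, 3)):
            raise ValueError("accel/gyro/mag must all be (n, 3) matching t")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise NonMonotoneTime(f"timestamps of node {self.node_id!r} not strictly increasing")

    def __len__(self):
        return len(self.t)

    def replace(self, **kw) -> "ImuTrace":
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class OrientationTrack:
    """Per-frame sensor→global quaternions plus the fixed sensor→body offset."""

    t: np.ndarray
    qSG: np.ndarray                      # (n, 4) scalar-first, unit norm
    qSB: Optional[Quaternion] = None     # fixed mount offset, if captured

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "qSG", np.asarray(self.qSG, dtype=float))

    def __len__(self):
        return len(self.t)

    def quaternion(self, i: int) -> Quaternion:
        return Quaternion.from_array(self.qSG[i])

    def body_to_global(self) -> np.ndarray:
        """qBG(t) = qSG(t) ⊗ qSB* frame-wise; identity offset if none captured."""
        if self.qSB is None:
            return self.qSG.copy()
        qsb_conj = _qconj(self.qSB.as_array())
        return np.array([_normalize(_qmult(q, qsb_conj)) for q in self.qSG])

    def with_mount(self, qSB: Quaternion) -> "OrientationTrack":
        return OrientationTrack(self.t, self.qSG, qSB)


# ---------------------------------------------------------------------------
# Initial attitude from gravity + magnetic field

def initial_euler(accel, mag, static_tol: float = 0.2) -> EulerAngles:
    """Static attitude from one accelerometer + magnetometer sample.

    roll  = arctan2(ay, az)
    pitch = arcsin(-ax / |a|)         (argument clipped to [-1, 1])
    yaw   = -arctan2(hGy, hGx)        with (hGx, hGy) the tilt-compensated
                                      horizontal field components

    Raises NotStatic if the accelerometer norm deviates from 1 g by more than
    ``static_tol`` (default 20%) — the gravity-only model does not hold during
    motion.
    """
    a = np.asarray(accel, dtype=float)
    h = np.asarray(mag, dtype=float)
    a_norm = np.linalg.norm(a)
    if abs(a_norm - 1.0) > static_tol:
        raise NotStatic(f"|accel| = {a_norm:.3f} g outside 1 ± {static_tol:g}")
    if np.linalg.norm(h) == 0.0:
        raise ZeroVector("magnetometer sample is zero")

    roll = math.atan2(a[1], a[2])
    pitch = math.asin(max(-1.0, min(1.0, -a[0] / a_norm)))

    st, ct = math.sin(pitch), math.cos(pitch)
    sr, cr = math.sin(roll), math.cos(roll)
    hGx = h[0] * ct + h[1] * st * sr + h[2] * st * cr
    hGy = h[1] * cr - h[2] * sr
    yaw = -math.atan2(hGy, hGx)
    return EulerAngles(roll, pitch, yaw)


def initial_quaternion(accel, mag, static_tol: float = 0.2) -> Quaternion:
    """Initial sensor→global quaternion: from_euler ∘ initial_euler."""
    return Quaternion.from_euler(initial_euler(accel, mag, static_tol))


# ---------------------------------------------------------------------------
# Gradient-descent objective

def _objective(q: np.ndarray, nG: np.ndarray, nS: np.ndarray) -> np.ndarray:
    """f = vec(q* ⊗ (0,nG) ⊗ q) - nS, zero iff q maps nS onto nG."""
    return _rotate_inv(q, nG) - nS


def _objective_jacobian(q: np.ndarray, nG: np.ndarray) -> np.ndarray:
    """Analytic 3x4 Jacobian of ``R(q)^T nG`` with respect to (q0..q3)."""
    w, x, y, z = q
    nx, ny, nz = nG
    return np.array([
        [2 * (z * ny - y * nz),
         2 * (y * ny + z * nz),
         -4 * y * nx + 2 * x * ny - 2 * w * nz,
         -4 * z * nx + 2 * w * ny + 2 * x * nz],
        [2 * (x * nz - z * nx),
         2 * y * nx - 4 * x * ny + 2 * w * nz,
         2 * (x * nx + z * nz),
         -2 * w * nx - 4 * z * ny + 2 * y * nz],
        [2 * (y * nx - x * ny),
         2 * z * nx - 2 * w * ny - 4 * x * nz,
         2 * w * nx + 2 * z * ny - 4 * y * nz,
         2 * (x * nx + y * ny)],
    ])


def objective_error(q: Quaternion, nG, nS) -> np.ndarray:
    """Residual of the field-alignment objective for one reference direction."""
    nG = np.asarray(nG, dtype=float)
    nS = np.asarray(nS, dtype=float)
    gnorm, snorm = np.linalg.norm(nG), np.linalg.norm(nS)
    if gnorm == 0.0 or snorm == 0.0:
        raise ZeroVector("field direction with zero norm")
    return _objective(q.as_array(), nG / gnorm, nS / snorm)


def _marg_gradient(q: np.ndarray, a_unit: np.ndarray, m_unit: np.ndarray) -> np.ndarray:
    """Stacked gravity + magnetic gradient ∇f = J^T f (4-vector).

    Gravity reference is (0,0,1); the magnetic reference (bx, 0, bz) is the
    measured field rotated into the global frame by the current estimate and
    flattened onto the x-z plane, which makes yaw the only angle the
    magnetometer can pull on.
    """
    g_ref = np.array([0.0, 0.0, 1.0])
    h = _rotate(q, m_unit)
    b_ref = np.array([math.hypot(h[0], h[1]), 0.0, h[2]])

    f_g = _objective(q, g_ref, a_unit)
    f_b = _objective(q, b_ref, m_unit)
    grad = (_objective_jacobian(q, g_ref).T @ f_g
            + _objective_jacobian(q, b_ref).T @ f_b)
    return grad


def gradient_step(q: Quaternion, accel, mag, xi: float = 0.1) -> Quaternion:
    """One normalized gradient-descent iteration toward the static attitude.

    q ← normalize(q − ξ ∇f / ||∇f||).  Skipped (q returned unchanged) when the
    gradient norm is below 1e-12, i.e. already at the optimum.
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    a_n, m_n = np.linalg.norm(a), np.linalg.norm(m)
    if a_n == 0.0 or m_n == 0.0:
        raise ZeroVector("accelerometer or magnetometer sample is zero")
    qa = q.as_array()
    grad = _marg_gradient(qa, a / a_n, m / m_n)
    gnorm = np.linalg.norm(grad)
    if gnorm < 1e-12:
        return q
    return Quaternion.from_array(_normalize(qa - xi * grad / gnorm))


def solve_static(accel, mag, q0: Optional[Quaternion] = None,
                 xi: float = 0.1, iters: int = 50) -> Quaternion:
    """Iterate ``gradient_step`` to the static optimum with backtracking.

    A fixed normalized step of size ξ orbits the optimum at a distance of
    order ξ, so the step gain is halved whenever an iteration fails to reduce
    the stacked objective norm; the schedule converges well inside the fixed
    step's plateau while each individual update remains the plain normalized
    gradient iteration.
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    a_u = a / np.linalg.norm(a)
    m_u = m / np.linalg.norm(m)

    def cost(qq: Quaternion) -> float:
        q = qq.as_array()
        g_ref = np.array([0.0, 0.0, 1.0])
        h = _rotate(q, m_u)
        b_ref = np.array([math.hypot(h[0], h[1]), 0.0, h[2]])
        return float(np.linalg.norm(_objective(q, g_ref, a_u))
                     + np.linalg.norm(_objective(q, b_ref, m_u)))

    q = q0 if q0 is not None else initial_quaternion(a, m)
    best = cost(q)
    for _ in range(iters):
        trial = gradient_step(q, a, m, xi)
        c = cost(trial)
        if c < best:
            q, best = trial, c
        else:
            xi *= 0.5
            if xi < 1e-12:
                break
    return q


def fuse_trace(trace: ImuTrace, q0: Quaternion, beta: float = 0.1) -> OrientationTrack:
    """Fuse a calibrated 9-axis trace into per-frame sensor→global quaternions.

    Per frame: quaternion rate from the gyroscope, q̇ = ½ q ⊗ (0, ω) with ω in
    rad/s, minus β times the normalized gravity+magnetic gradient; integrated
    at dt = 1/rate and renormalized.  β = 0 degenerates to pure gyro
    integration (useful as a drift baseline).

    The first output frame is ``q0`` itself; corrections start at frame 1.
    """
    n = len(trace)
    dt = 1.0 / trace.rate
    q = q0.as_array().copy()
    out = np.empty((n, 4))
    out[0] = q
    gyro_rad = trace.gyro * DEG
    for i in range(1, n):
        w = gyro_rad[i]
        qdot = 0.5 * _qmult(q, np.array([0.0, w[0], w[1], w[2]]))
        a = trace.accel[i]
        m = trace.mag[i]
        a_n = np.linalg.norm(a)
        m_n = np.linalg.norm(m)
        if beta > 0.0 and a_n > 0.0 and m_n > 0.0:
            grad = _marg_gradient(q, a / a_n, m / m_n)
            gnorm = np.linalg.norm(grad)
            if gnorm > 1e-12:
                qdot -= beta * grad / gnorm
        q = _normalize(q + qdot * dt)
        out[i] = q
    # canonical sign per frame keeps downstream comparisons deterministic
    out[out[:, 0] < 0] *= -1
    return OrientationTrack(trace.t.copy(), out)


def sensor_to_body(track: OrientationTrack,
                   still_seconds: float = 1.0,
                   rate: Optional[float] = None) -> Quaternion:
    """Capture the fixed sensor→body mount offset from the neutral still pose.

    During the north-facing neutral stance the body frame coincides with the
    global frame, so qSB = qSG there; averaging the per-frame estimates over
    the still window suppresses measurement noise.  The quaternion mean is the
    sign-aligned, renormalized arithmetic mean (adequate for tightly clustered
    rotations).

    Raises StillIntervalTooShort when the track holds less than
    ``still_seconds`` of frames.
    """
    if rate is None:
        if len(track) > 1:
            rate = 1.0 / float(np.median(np.diff(track.t)))
        else:
            rate = 1.0
    n_still = int(round(still_seconds * rate))
    if n_still < 1 or len(track) < n_still:
        raise StillIntervalTooShort(
            f"track holds {len(track)} frames, need {n_still} "
            f"({still_seconds:g} s at {rate:g} Hz)")
    qs = track.qSG[:n_still].copy()
    qs[qs @ qs[0] < 0] *= -1
    return Quaternion.from_array(_normalize(qs.mean(axis=0)))
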