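"""Ground-truth motion scripting and MARG sensor synthesis.

Every downstream stage is validated against traces produced here: a
``MotionScript`` prescribes per-segment body→global quaternion trajectories
(parametric rotation waveforms or keyframed Euler angles), and
``synthesize_trace`` inverts the measurement models — gyro from the exact
frame-to-frame quaternion increments, accelerometer from the sensor-frame
gravity direction (the recorded tasks are seated, so linear acceleration is
omitted), magnetometer from the sensor-frame earth field pushed through the
inverse of the hard-iron/axis-scale calibration map — then injects biases and
white noise per the sensor error models.

``generate_task_dataset`` emits labeled joint-angle series for the four work
tasks (recite / reading comprehension / browse / music) from per-task posture
recipes with within-class Gaussian jitter, and ``hermite_resample`` is the
piecewise-cubic Hermite resampler used to align streams recorded at different
rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from posturekit.calibration import MagCalibration
from posturekit.errors import TooFewPoints
from posturekit.fusion import ImuTrace
from posturekit.quat import Quaternion, _normalize, _qconj, _qmult, _rotate_inv
from posturekit.skeleton import ANGLE_CHANNELS, JointAngleSeries

__all__ = [
    "SegmentMotion",
    "ComposedMotion",
    "MotionScript",
    "SensorCorruption",
    "TaskRecipe",
    "DEFAULT_EARTH_FIELD",
    "DEFAULT_TASK_RECIPES",
    "synthesize_trace",
    "generate_task_dataset",
    "hermite_resample",
]

DEG = math.pi / 180.0

#: mid-latitude field with a downward dip component, gauss (north-east-down)
DEFAULT_EARTH_FIELD = np.array([0.25, 0.0, 0.4])

MAX_INTERFRAME_DEG = 10.0


@dataclass(frozen=True)
class SegmentMotion:
    """One segment's rotation trajectory about a fixed axis.

    angle(t) = offset + amp * sin(2*pi*freq*t + phase), degrees; or keyframed
    angles interpolated with a cubic Hermite spline when ``key_t`` is given.

    ``ramp = (t_start, t_rise)`` multiplies the whole angle by a smoothstep
    envelope that is 0 until ``t_start`` and 1 after ``t_start + t_rise``, so
    a motion can begin from the neutral stance without a pose discontinuity.
    """

    axis: np.ndarray
    offset_deg: float = 0.0
    amp_deg: float = 0.0
    freq_hz: float = 0.0
    phase: float = 0.0
    key_t: Optional[np.ndarray] = None
    key_deg: Optional[np.ndarray] = None
    ramp: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("zero rotation axis")
        object.__setattr__(self, "axis", ax / n)

    @classmethod
    def static(cls, axis=(0, 1, 0), angle_deg: float = 0.0) -> "SegmentMotion":
        return cls(np.asarray(axis, float), offset_deg=angle_deg)

    @classmethod
    def sinusoid(cls, axis, offset_deg, amp_deg, freq_hz, phase=0.0) -> "SegmentMotion":
        return cls(np.asarray(axis, float), offset_deg, amp_deg, freq_hz, phase)

    @classmethod
    def keyframes(cls, axis, times, angles_deg) -> "SegmentMotion":
        t = np.asarray(times, float)
        a = np.asarray(angles_deg, float)
        if len(t) < 2:
            raise ValueError("need at least two keyframes")
        return cls(np.asarray(axis, float), key_t=t, key_deg=a)

    def _with_ramp(self, ramp: Tuple[float, float]) -> "SegmentMotion":
        return SegmentMotion(self.axis, self.offset_deg, self.amp_deg,
                             self.freq_hz, self.phase, self.key_t, self.key_deg,
                             ramp)

    def angles(self, t: np.ndarray) -> np.ndarray:
        if self.key_t is not None:
            interp = PchipInterpolator(self.key_t, self.key_deg, extrapolate=True)
            a = interp(t)
        else:
            a = self.offset_deg + self.amp_deg * np.sin(
                2 * math.pi * self.freq_hz * t + self.phase)
        if self.ramp is not None:
            t0, rise = self.ramp
            s = np.clip((t - t0) / max(rise, 1e-9), 0.0, 1.0)
            a = a * (s * s * (3.0 - 2.0 * s))
        return a

    def quaternions(self, t: np.ndarray) -> np.ndarray:
        half = 0.5 * self.angles(t) * DEG
        q = np.zeros((len(t), 4))
        q[:, 0] = np.cos(half)
        q[:, 1:] = np.sin(half)[:, None] * self.axis
        return q


@dataclass(frozen=True)
class ComposedMotion:
    """Product of two axis rotations, ``outer(t) ⊗ inner(t)``.

    Lets a script sweep full orientation coverage (e.g. a yaw sweep composed
    with a pitch sweep for a magnetometer calibration wave) where a single
    fixed axis would only trace a planar ring of field directions.
    """

    outer: "SegmentMotion"
    inner: "SegmentMotion"

    def quaternions(self, t: np.ndarray) -> np.ndarray:
        qo = self.outer.quaternions(t)
        qi = self.inner.quaternions(t)
        return np.array([_normalize(_qmult(a, b)) for a, b in zip(qo, qi)])


@dataclass(frozen=True)
class MotionScript:
    """Per-segment body→global quaternion trajectories on a uniform clock."""

    motions: Dict[str, SegmentMotion]
    duration: float
    rate: float

    def times(self) -> np.ndarray:
        n = int(round(self.duration * self.rate))
        return np.arange(n) / self.rate

    def quaternions(self, segment: str) -> np.ndarray:
        t = self.times()
        q = self.motions[segment].quaternions(t)
        # continuity guard: scripted motion must stay resolvable at this rate
        dots = np.abs(np.sum(q[1:] * q[:-1], axis=1)).clip(0, 1)
        step = 2 * np.degrees(np.arccos(dots))
        if step.size and step.max() > MAX_INTERFRAME_DEG:
            raise ValueError(
                f"segment {segment!r}: inter-frame rotation {step.max():.1f} deg "
                f"exceeds {MAX_INTERFRAME_DEG} deg; raise the rate")
        return q

    def all_quaternions(self) -> Dict[str, np.ndarray]:
        return {name: self.quaternions(name) for name in self.motions}

    @classmethod
    def static_pose(cls, segments: List[str], duration: float, rate: float,
                    ) -> "MotionScript":
        return cls({s: SegmentMotion.static() for s in segments}, duration, rate)


@dataclass(frozen=True)
class SensorCorruption:
    """Sensor error injection: biases, axis distortions and white noise."""

    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))  # deg/s
    gyro_noise_std: float = 0.0                                         # deg/s
    accel_noise_std: float = 0.0                                        # g
    mag_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))  # gauss
    mag_scales: np.ndarray = field(default_factory=lambda: np.ones(3))
    mag_noise_std: float = 0.0                                          # gauss

    def __post_init__(self):
        object.__setattr__(self, "gyro_bias", np.asarray(self.gyro_bias, float))
        object.__setattr__(self, "mag_offset", np.asarray(self.mag_offset, float))
        object.__setattr__(self, "mag_scales", np.asarray(self.mag_scales, float))
        if min(self.gyro_noise_std, self.accel_noise_std, self.mag_noise_std) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def none(cls) -> "SensorCorruption":
        return cls()

    @classmethod
    def default(cls) -> "SensorCorruption":
        """Error magnitudes on the scale of a consumer MARG node."""
        return cls(gyro_bias=np.array([0.5, -0.3, 0.1]), gyro_noise_std=0.04,
                   accel_noise_std=0.005,
                   mag_offset=np.array([0.2, -0.1, 0.3]),
                   mag_scales=np.array([1.05, 1.0, 0.95]),
                   mag_noise_std=0.005)


def _body_rates(q: np.ndarray, dt: float) -> np.ndarray:
    """Sensor-frame angular velocity (rad/s) whose integration reproduces q.

    gyro[i] is the backward increment q[i-1] → q[i]:
    q[i] = q[i-1] ⊗ exp(½ ω dt); gyro[0] repeats gyro[1].
    """
    n = len(q)
    w = np.zeros((n, 3))
    for i in range(1, n):
        dq = _normalize(_qmult(_qconj(q[i - 1]), q[i]))
        if dq[0] < 0:
            dq = -dq
        vnorm = np.linalg.norm(dq[1:])
        angle = 2.0 * math.atan2(vnorm, dq[0])
        if vnorm > 1e-15:
            w[i] = (angle / dt) * dq[1:] / vnorm
    if n > 1:
        w[0] = w[1]
    return w


def synthesize_trace(script: MotionScript,
                     segment: str,
                     qSB: Optional[Quaternion] = None,
                     corruption: Optional[SensorCorruption] = None,
                     field_vec=DEFAULT_EARTH_FIELD,
                     seed: int = 0,
                     node_id: Optional[str] = None,
                     ) -> Tuple[ImuTrace, np.ndarray]:
    """Synthesize one node's 9-axis trace from a scripted segment trajectory.

    Returns the (possibly corrupted) ImuTrace and the ground-truth
    sensor→global quaternion track ``qSG = qBG ⊗ qSB``.

    The magnetometer is distorted with the *inverse* of the calibration map
    (offset plus per-axis scaling), so fitting the ellipsoid to the synthetic
    trace must recover ``corruption.mag_offset`` and ``mag_scales``.
    """
    corruption = corruption or SensorCorruption.none()
    qSB_arr = (qSB or Quaternion.identity()).as_array()
    field_vec = np.asarray(field_vec, dtype=float)
    rng = np.random.default_rng(seed)

    qBG = script.quaternions(segment)
    qSG = np.array([_normalize(_qmult(q, qSB_arr)) for q in qBG])
    n = len(qSG)
    dt = 1.0 / script.rate

    gravity = np.array([0.0, 0.0, 1.0])
    accel = np.array([_rotate_inv(q, gravity) for q in qSG])
    mag_true = np.array([_rotate_inv(q, field_vec) for q in qSG])

    gyro = np.degrees(_body_rates(qSG, dt))
    gyro = gyro + corruption.gyro_bias
    if corruption.gyro_noise_std > 0:
        gyro = gyro + rng.normal(0, corruption.gyro_noise_std, (n, 3))
    if corruption.accel_noise_std > 0:
        accel = accel + rng.normal(0, corruption.accel_noise_std, (n, 3))
    mag = corruption.mag_offset + corruption.mag_scales * mag_true
    if corruption.mag_noise_std > 0:
        mag = mag + rng.normal(0, corruption.mag_noise_std, (n, 3))

    trace = ImuTrace(node_id or segment, script.rate, script.times(),
                     accel, gyro, mag)
    return trace, qSG


def inverse_calibration(corruption: SensorCorruption, R: float) -> MagCalibration:
    """The MagCalibration that exactly undoes a corruption's mag distortion of
    a field of modulus R."""
    return MagCalibration(corruption.mag_offset, corruption.mag_scales * R, R)


# ---------------------------------------------------------------------------
# Labeled task dataset

@dataclass(frozen=True)
class TaskRecipe:
    """Per-channel posture waveform of one work task.

    ``channels`` maps an angle channel to (mean_deg, amp_deg, freq_hz);
    channels not listed sit at the seated baseline.  Within-class variation:
    each generated series jitters the mean by ``mean_jitter_deg`` (1 sd), the
    amplitude by 10% and the frequency by 5%, plus white measurement noise of
    ``angle_noise_deg`` on every sample.
    """

    name: str
    channels: Dict[str, Tuple[float, float, float]]
    mean_jitter_deg: float = 2.0
    amp_jitter_frac: float = 0.10
    freq_jitter_frac: float = 0.05
    angle_noise_deg: float = 0.5


#: seated baseline per channel (degrees): trunk upright, knees and hips at 90
_BASELINE = {"BF": 175.0, "WF": 95.0, "SFl": 165.0, "SFr": 165.0,
             "EFl": 60.0, "EFr": 60.0, "KFl": 90.0, "KFr": 90.0}

DEFAULT_TASK_RECIPES: Dict[int, TaskRecipe] = {
    # recite: upright, small fast bilateral elbow oscillation (page turning,
    # gesturing while reciting)
    1: TaskRecipe("recite", {
        "EFl": (75.0, 8.0, 2.0), "EFr": (75.0, 8.0, 2.0),
        "BF": (168.0, 2.0, 0.5), "WF": (92.0, 1.5, 0.5),
    }),
    # reading comprehension: forward trunk lean, right-arm writing motion
    2: TaskRecipe("reading_comprehension", {
        "EFr": (95.0, 6.0, 1.2), "EFl": (65.0, 2.0, 0.3),
        "BF": (155.0, 3.0, 0.4), "WF": (85.0, 2.0, 0.4),
    }),
    # browse: near-still upright posture, occasional slow scroll of one arm
    3: TaskRecipe("browse", {
        "EFr": (110.0, 2.5, 0.5), "EFl": (60.0, 1.0, 0.2),
        "BF": (172.0, 1.5, 0.2), "WF": (96.0, 1.0, 0.2),
    }),
    # music: relaxed lean back with a large slow trunk sway, arms dropped
    4: TaskRecipe("music", {
        "BF": (160.0, 10.0, 0.3), "WF": (105.0, 6.0, 0.3),
        "EFl": (120.0, 3.0, 0.3), "EFr": (120.0, 3.0, 0.3),
    }),
}


def generate_task_dataset(n_per_class: int = 100,
                          recipes: Optional[Dict[int, TaskRecipe]] = None,
                          seed: int = 7,
                          rate: float = 400.0,
                          series_per_class: int = 5,
                          window_ms: float = 1000.0,
                          ) -> Dict[int, List[JointAngleSeries]]:
    """Labeled joint-angle series for the four work tasks.

    Each class contributes ``series_per_class`` independent recordings whose
    total 50%-overlap window count equals ``n_per_class``.  All randomness
    flows from ``seed``.
    """
    recipes = recipes or DEFAULT_TASK_RECIPES
    rng = np.random.default_rng(seed)
    w = int(round(window_ms / 1000.0 * rate))
    per_series = int(math.ceil(n_per_class / series_per_class))
    n_samples = (per_series + 1) * w // 2  # yields exactly per_series windows

    out: Dict[int, List[JointAngleSeries]] = {}
    for label in sorted(recipes):
        recipe = recipes[label]
        series_list = []
        for _ in range(series_per_class):
            t = np.arange(n_samples) / rate
            angles = {}
            for ch in ANGLE_CHANNELS:
                mean, amp, freq = recipe.channels.get(ch, (_BASELINE[ch], 0.0, 0.0))
                mean = mean + rng.normal(0, recipe.mean_jitter_deg)
                amp = amp * (1 + rng.normal(0, recipe.amp_jitter_frac))
                freq = freq * (1 + rng.normal(0, recipe.freq_jitter_frac))
                phase = rng.uniform(0, 2 * math.pi)
                y = mean + amp * np.sin(2 * math.pi * freq * t + phase)
                y = y + rng.normal(0, recipe.angle_noise_deg, n_samples)
                angles[ch] = np.clip(y, 0.0, 180.0)
            series_list.append(JointAngleSeries(t, angles, rate))
        out[label] = series_list
    return out


# ---------------------------------------------------------------------------
# Hermite resampling

def hermite_resample(t, values, target_rate: float,
                     monotone: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Resample a timestamped series onto a uniform grid at ``target_rate``
    with piecewise-cubic Hermite interpolation.

    Node derivatives come from the local cubic through each point's four
    nearest nodes, which makes the interpolant exact on cubic polynomials.
    With ``monotone=True`` a shape-preserving (PCHIP) derivative rule is used
    instead; it cannot overshoot monotone data but loses cubic exactness.

    ``values`` may be 1-D or (n, k); columns are resampled independently.
    Returns (new_t, new_values).

    Raises TooFewPoints for fewer than 4 samples.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise TooFewPoints(f"need >= 4 points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    n_new = int(math.floor((t[-1] - t[0]) * target_rate)) + 1
    t_new = t[0] + np.arange(n_new) / target_rate

    y2d = y.reshape(len(t), -1)
    out = np.empty((n_new, y2d.shape[1]))
    for j in range(y2d.shape[1]):
        col = y2d[:, j]
        if monotone:
            interp = PchipInterpolator(t, col)
        else:
            d = _local_cubic_derivatives(t, col)
            interp = CubicHermiteSpline(t, col, d)
        out[:, j] = interp(t_new)
    return t_new, out.reshape((n_new,) + y.shape[1:])


def _local_cubic_derivatives(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """dy/dt at every node from the cubic through its 4 nearest nodes
    (exact when the data are samples of a cubic polynomial)."""
    n = len(t)
    d = np.empty(n)
    for i in range(n):
        j = min(max(i - 1, 0), n - 4)
        ts = t[j:j + 4] - t[i]
        coeffs = np.linalg.solve(np.vander(ts, 4), y[j:j + 4])
        d[i] = coeffs[2]  # linear coefficient of the local cubic at ts = 0
    return d
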