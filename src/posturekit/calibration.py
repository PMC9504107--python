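"""Sensor error models and magnetometer hard-iron / ellipsoid calibration.

A magnetometer moved through all orientations in a constant field should trace
a sphere of radius R (the local field modulus).  Hard-iron offsets translate
that sphere and per-axis scale errors stretch it into an axis-aligned
ellipsoid:

    (Hx - ex)^2 / a^2 + (Hy - ey)^2 / b^2 + (Hz - ez)^2 / c^2 = R^2

``fit_ellipsoid`` recovers (ex, ey, ez, a, b, c, R) by linear least squares on
the expanded quadric (no cross terms: soft-iron is modelled as axis-aligned
scaling only), and ``apply_mag_calibration`` maps raw readings back onto the
R-sphere.  Gyro and accelerometer biases are estimated from an initial still
interval and subtracted; white noise is left for the orientation filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from posturekit.errors import DegenerateCoverage, StillIntervalTooShort

if TYPE_CHECKING:  # pragma: no cover
    from posturekit.fusion import ImuTrace

__all__ = [
    "MagCalibration",
    "InertialErrorModel",
    "fit_ellipsoid",
    "apply_mag_calibration",
    "correct_inertial",
    "estimate_inertial_errors",
]

MIN_SAMPLES = 9
MIN_STILL_SECONDS = 1.0


@dataclass(frozen=True)
class MagCalibration:
    """Hard-iron offsets, ellipsoid semiaxes and field modulus, all in gauss."""

    offsets: np.ndarray        # (ex, ey, ez)
    semiaxes: np.ndarray       # (a, b, c)
    field_modulus: float       # R
    residual_rms: float = 0.0  # RMS of the quadric residual over the fit set

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "semiaxes", np.asarray(self.semiaxes, dtype=float))
        if np.any(self.semiaxes <= 0):
            raise ValueError("semiaxes must be positive")
        if self.field_modulus <= 0:
            raise ValueError("field modulus must be positive")

    @classmethod
    def identity(cls, R: float = 1.0) -> "MagCalibration":
        return cls(np.zeros(3), np.full(3, R), R)

    def to_dict(self) -> dict:
        return {
            "offsets": [float(v) for v in self.offsets],
            "semiaxes": [float(v) for v in self.semiaxes],
            "field_modulus": float(self.field_modulus),
            "residual_rms": float(self.residual_rms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MagCalibration":
        return cls(np.asarray(d["offsets"], dtype=float),
                   np.asarray(d["semiaxes"], dtype=float),
                   float(d["field_modulus"]),
                   float(d.get("residual_rms", 0.0)))


@dataclass(frozen=True)
class InertialErrorModel:
    """Constant biases and white-noise levels of the inertial channels.

    Gyro terms in deg/s, accelerometer terms in g.  Noise standard deviations
    are diagnostic only: the orientation filter absorbs white noise, so
    ``correct_inertial`` subtracts the biases and nothing else.
    """

    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_noise_std: float = 0.0
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_noise_std: float = 0.0
    gravity: float = 1.0  # g, magnitude of the static specific-force reading

    def __post_init__(self):
        object.__setattr__(self, "gyro_bias", np.asarray(self.gyro_bias, dtype=float))
        object.__setattr__(self, "accel_bias", np.asarray(self.accel_bias, dtype=float))
        if self.gyro_noise_std < 0 or self.accel_noise_std < 0:
            raise ValueError("noise standard deviations must be non-negative")


def fit_ellipsoid(samples) -> MagCalibration:
    """Fit the axis-aligned ellipsoid to raw magnetometer readings.

    Parameters
    ----------
    samples : (n, 3) array-like of gauss readings, n >= 9, spanning a
        reasonable spread of directions (a planar wand-wave cannot constrain
        all six quadric parameters).

    Returns
    -------
    MagCalibration with R taken as the geometric mean of the semiaxes (for a
    true sphere a = b = c = R exactly).

    Raises
    ------
    DegenerateCoverage
        If fewer than 9 samples are given or the direction scatter is
        rank-deficient (near-planar coverage).
    """
    H = np.asarray(samples, dtype=float)
    if H.ndim != 2 or H.shape[1] != 3 or H.shape[0] < MIN_SAMPLES:
        raise DegenerateCoverage(
            f"need at least {MIN_SAMPLES} 3-vector samples, got {H.shape}")

    centered = H - H.mean(axis=0)
    scatter_eigs = np.linalg.eigvalsh(centered.T @ centered)
    if scatter_eigs[0] < 1e-9 * max(scatter_eigs[-1], 1e-30):
        raise DegenerateCoverage(
            "sample scatter matrix is rank-deficient; wave covered too few directions")

    # Expanded quadric  p1 x^2 + p2 y^2 + p3 z^2 + p4 x + p5 y + p6 z = 1
    x, y, z = H[:, 0], H[:, 1], H[:, 2]
    D = np.column_stack([x * x, y * y, z * z, x, y, z])
    p, *_ = np.linalg.lstsq(D, np.ones(len(H)), rcond=None)
    if np.any(p[:3] <= 0):
        raise DegenerateCoverage("fitted quadric is not an ellipsoid")

    center = -p[3:] / (2.0 * p[:3])
    # evaluate the constant: p·q(center) shifts the RHS
    g = 1.0 + np.sum(p[:3] * center**2)
    semi_sq = g / p[:3]
    if np.any(semi_sq <= 0):
        raise DegenerateCoverage("fitted quadric is not an ellipsoid")
    semiaxes = np.sqrt(semi_sq)
    R = float(np.cbrt(semiaxes.prod()))

    resid = ((H - center) ** 2 / semi_sq).sum(axis=1) - 1.0
    rms = float(np.sqrt(np.mean(resid**2)))
    return MagCalibration(center, semiaxes, R, rms)


def apply_mag_calibration(cal: MagCalibration, raw) -> np.ndarray:
    """Map raw readings onto the R-sphere: component-wise (raw - e) * R / axis.

    Accepts a single 3-vector or an (n, 3) array.
    """
    raw = np.asarray(raw, dtype=float)
    return (raw - cal.offsets) * (cal.field_modulus / cal.semiaxes)


def estimate_inertial_errors(trace: "ImuTrace",
                             still_seconds: float = MIN_STILL_SECONDS,
                             ) -> InertialErrorModel:
    """Estimate gyro and accelerometer biases from the initial still interval.

    The wearer stands still for a few seconds at the start of every recording;
    over that interval the true angular rate is zero, so the mean gyro reading
    is the bias.  The accelerometer should read a 1 g specific force; its bias
    is the mean reading minus the unit-magnitude vector along the mean
    direction (direction is attitude, magnitude error is bias).

    Raises
    ------
    StillIntervalTooShort
        If the trace holds fewer than ``still_seconds`` of samples.
    """
    n_still = int(round(still_seconds * trace.rate))
    if len(trace) < n_still or still_seconds < MIN_STILL_SECONDS:
        raise StillIntervalTooShort(
            f"need >= {MIN_STILL_SECONDS:.1f} s of still samples, "
            f"got {len(trace) / trace.rate:.2f} s (requested {still_seconds:.2f} s)")

    gyro_still = trace.gyro[:n_still]
    accel_still = trace.accel[:n_still]
    gyro_bias = gyro_still.mean(axis=0)
    gyro_noise = float(gyro_still.std(axis=0).mean())

    a_mean = accel_still.mean(axis=0)
    a_norm = np.linalg.norm(a_mean)
    accel_bias = a_mean - a_mean / a_norm if a_norm > 0 else np.zeros(3)
    accel_noise = float(accel_still.std(axis=0).mean())
    return InertialErrorModel(gyro_bias, gyro_noise, accel_bias, accel_noise)


def correct_inertial(model: InertialErrorModel, trace: "ImuTrace") -> "ImuTrace":
    """Subtract the estimated gyro and accelerometer biases from a trace."""
    return trace.replace(
        gyro=trace.gyro - model.gyro_bias,
        accel=trace.accel - model.accel_bias,
    )
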