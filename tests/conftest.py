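"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the package's own quaternion code:
rotations are built and composed as explicit 3x3 matrices so quaternion
operations can be validated against an independent formulation.
"""

import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Rotation-matrix oracle (independent of posturekit.quat)

def rotmat_x(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rotmat_y(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rotmat_z(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotmat_zyx(roll, pitch, yaw):
    """Rz(yaw) @ Ry(pitch) @ Rx(roll), the ZYX Euler composition."""
    return rotmat_z(yaw) @ rotmat_y(pitch) @ rotmat_x(roll)


def quat_to_matrix_oracle(q):
    """3x3 rotation matrix of a scalar-first quaternion, written from the
    textbook entries (not the package's method)."""
    w, x, y, z = np.asarray(q, dtype=float)
    return np.array([
        [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
    ])


def matrix_to_quat_oracle(R):
    """Shepperd's method, scalar-first, positive scalar part."""
    tr = np.trace(R)
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2
        q = np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def random_unit_quat(rng, n=None):
    """Uniform random unit quaternion(s), canonical positive scalar."""
    q = rng.normal(size=(4,) if n is None else (n, 4))
    q = np.atleast_2d(q)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[q[:, 0] < 0] *= -1
    return q[0] if n is None else q
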