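"""15-segment rigid body model, pelvis-rooted forward kinematics and joint angles.

The body is a rigid tree rooted at the pelvis.  Each segment carries a length
and a neutral-pose unit direction in the global north-east-down frame (trunk
and head point up = -z, arms and legs hang down = +z, shoulders reach
mediolaterally).  Given per-frame body-segment→global quaternions, endpoint
positions propagate depth-first from the pelvis:

    D1(t) = D0(t) + q(t) ⊗ (0, l·û) ⊗ q(t)*,   child D0(t) := parent D1(t)

so connectivity and segment lengths are conserved by construction.  Joint
flexion angles are the inverse cosine of the normalized dot product of the two
adjacent segment vectors, in degrees within [0, 180].

Segments without a worn node (head, shoulders — and waist/chest when only ten
nodes are worn) inherit the orientation of the chest node, or the pelvis for
the waist, mirroring how a sparse node set is mapped onto the full tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from posturekit.errors import MissingSegmentPose, ZeroVector
from posturekit.quat import _rotate

__all__ = [
    "Segment",
    "BodyModel",
    "SegmentPose",
    "JointAngleSeries",
    "default_body_model",
    "propagate_positions",
    "joint_angle",
    "joint_angle_series",
    "ANGLE_CHANNELS",
]

#: joint-angle CSV column order
ANGLE_CHANNELS = ["BF", "WF", "SFl", "SFr", "EFl", "EFr", "KFl", "KFr"]

_UP = np.array([0.0, 0.0, -1.0])     # NED: up is -z
_DOWN = np.array([0.0, 0.0, 1.0])
_LEFT = np.array([0.0, -1.0, 0.0])   # y east = wearer's right when facing north
_RIGHT = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class Segment:
    name: str
    parent: Optional[str]          # None for the root (pelvis)
    length: float                  # meters
    direction: np.ndarray          # unit neutral-pose direction, global frame
    node: Optional[str] = None     # worn node id, or None to inherit

    def __post_init__(self):
        object.__setattr__(self, "direction",
                           np.asarray(self.direction, dtype=float))
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be positive")
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError(f"segment {self.name!r}: zero direction")
        object.__setattr__(self, "direction", self.direction / n)


class BodyModel:
    """Rigid tree of exactly 15 segments rooted at the pelvis."""

    N_SEGMENTS = 15

    def __init__(self, segments: List[Segment]):
        if len(segments) != self.N_SEGMENTS:
            raise ValueError(f"body model needs exactly {self.N_SEGMENTS} segments, "
                             f"got {len(segments)}")
        self.segments: Dict[str, Segment] = {s.name: s for s in segments}
        if len(self.segments) != len(segments):
            raise ValueError("duplicate segment names")
        roots = [s for s in segments if s.parent is None]
        if len(roots) != 1:
            raise ValueError("body model needs a single root segment")
        self.root = roots[0].name
        # verify every segment reaches the root (tree, no cycles)
        order: List[str] = []
        for s in segments:
            seen, cur = set(), s
            while cur.parent is not None:
                if cur.name in seen:
                    raise ValueError(f"cycle through segment {cur.name!r}")
                seen.add(cur.name)
                if cur.parent not in self.segments:
                    raise ValueError(f"segment {cur.name!r} has unknown parent "
                                     f"{cur.parent!r}")
                cur = self.segments[cur.parent]
        # depth-first traversal order, parents before children
        children: Dict[str, List[str]] = {name: [] for name in self.segments}
        for s in segments:
            if s.parent is not None:
                children[s.parent].append(s.name)
        stack = [self.root]
        while stack:
            name = stack.pop()
            order.append(name)
            stack.extend(reversed(children[name]))
        self.traversal = order

    def resolve_node(self, name: str, inherit: Dict[str, str]) -> str:
        """Segment whose orientation source ultimately drives ``name``."""
        while name in inherit:
            name = inherit[name]
        return name

    def to_dict(self) -> dict:
        return {"segments": [
            {"name": s.name, "parent": s.parent, "length": float(s.length),
             "direction": [float(v) for v in s.direction], "node": s.node}
            for s in self.segments.values()]}

    @classmethod
    def from_dict(cls, d: dict) -> "BodyModel":
        return cls([Segment(e["name"], e["parent"], e["length"],
                            np.asarray(e["direction"], dtype=float), e.get("node"))
                    for e in d["segments"]])


#: anthropometric segment lengths as fractions of stature (rounded field-standard
#: proportions; overridable per segment)
_LENGTH_FRACTIONS = {
    "pelvis": 0.060, "waist": 0.120, "chest": 0.150, "neck": 0.052, "head": 0.130,
    "shoulder_l": 0.100, "shoulder_r": 0.100,
    "upper_arm_l": 0.172, "upper_arm_r": 0.172,
    "forearm_l": 0.157, "forearm_r": 0.157,
    "thigh_l": 0.245, "thigh_r": 0.245,
    "calf_l": 0.246, "calf_r": 0.246,
}

#: segments without their own worn node inherit orientation from these
DEFAULT_INHERITANCE = {
    "neck": "chest",
    "head": "chest",
    "shoulder_l": "chest",
    "shoulder_r": "chest",
    "waist": "pelvis",
}


def default_body_model(stature: float = 1.70,
                       lengths: Optional[Dict[str, float]] = None) -> BodyModel:
    """The ten-node body model: trunk chain, arms via shoulders, legs.

    Segment lengths default to standard anthropometric fractions of
    ``stature`` (meters); ``lengths`` overrides individual segments.
    """
    L = {k: v * stature for k, v in _LENGTH_FRACTIONS.items()}
    if lengths:
        L.update(lengths)
    specs = [
        ("pelvis", None, _UP, "pelvis"),
        ("waist", "pelvis", _UP, None),
        ("chest", "waist", _UP, "chest"),
        ("neck", "chest", _UP, None),
        ("head", "neck", _UP, None),
        ("shoulder_l", "chest", _LEFT, None),
        ("upper_arm_l", "shoulder_l", _DOWN, "upper_arm_l"),
        ("forearm_l", "upper_arm_l", _DOWN, "forearm_l"),
        ("shoulder_r", "chest", _RIGHT, None),
        ("upper_arm_r", "shoulder_r", _DOWN, "upper_arm_r"),
        ("forearm_r", "upper_arm_r", _DOWN, "forearm_r"),
        ("thigh_l", "pelvis", _DOWN, "thigh_l"),
        ("calf_l", "thigh_l", _DOWN, "calf_l"),
        ("thigh_r", "pelvis", _DOWN, "thigh_r"),
        ("calf_r", "thigh_r", _DOWN, "calf_r"),
    ]
    return BodyModel([Segment(n, p, L[n], d, node) for n, p, d, node in specs])


@dataclass
class SegmentPose:
    """Global start/end positions and orientations of every segment, per frame."""

    t: np.ndarray
    start: Dict[str, np.ndarray] = field(default_factory=dict)   # (n, 3) each
    end: Dict[str, np.ndarray] = field(default_factory=dict)
    quat: Dict[str, np.ndarray] = field(default_factory=dict)    # (n, 4) each

    def __len__(self):
        return len(self.t)

    def segment_vector(self, name: str) -> np.ndarray:
        """(n, 3) vector D1 - D0 of a segment over all frames."""
        return self.end[name] - self.start[name]


@dataclass
class JointAngleSeries:
    """Flexion-angle time series in degrees, one column per ANGLE_CHANNELS."""

    t: np.ndarray
    angles: Dict[str, np.ndarray]
    rate: float

    def __len__(self):
        return len(self.t)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.angles[c] for c in ANGLE_CHANNELS])


def propagate_positions(model: BodyModel,
                        poses: Dict[str, np.ndarray],
                        root_position=(0.0, 0.0, 0.0),
                        inherit: Optional[Dict[str, str]] = None) -> SegmentPose:
    """Forward kinematics: per-frame endpoint positions for every segment.

    Parameters
    ----------
    poses : mapping segment name -> (n, 4) body→global quaternion track.
        Segments missing from the mapping use the ``inherit`` table
        (default: head/shoulders from chest, waist from pelvis).
    root_position : fixed global position of the pelvis start (the recorded
        tasks are seated, so the root does not translate).

    Raises
    ------
    MissingSegmentPose
        If a segment has no quaternions and no segment to inherit from.
    """
    inherit = DEFAULT_INHERITANCE if inherit is None else inherit
    resolved: Dict[str, np.ndarray] = {}
    n = None
    for name in model.traversal:
        src = name
        while src not in poses:
            if src not in inherit:
                raise MissingSegmentPose(
                    f"segment {name!r} has no orientation track and no inheritance")
            src = inherit[src]
        q = np.asarray(poses[src], dtype=float)
        if n is None:
            n = len(q)
        elif len(q) != n:
            raise ValueError("all quaternion tracks must have equal length")
        resolved[name] = q

    t = np.arange(n, dtype=float)
    out = SegmentPose(t=t)
    root_pos = np.broadcast_to(np.asarray(root_position, dtype=float), (n, 3))
    for name in model.traversal:
        seg = model.segments[name]
        q = resolved[name]
        offset = np.array([_rotate(q[i], seg.length * seg.direction)
                           for i in range(n)])
        d0 = root_pos if seg.parent is None else out.end[seg.parent]
        out.start[name] = np.asarray(d0, dtype=float).copy()
        out.end[name] = out.start[name] + offset
        out.quat[name] = q
    return out


def joint_angle(parent_vec, child_vec) -> float:
    """Angle in degrees between two segment vectors: arccos of the clamped
    normalized dot product, in [0, 180]."""
    a = np.asarray(parent_vec, dtype=float)
    b = np.asarray(child_vec, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroVector("joint angle undefined for zero-length vector")
    c = float(np.dot(a, b) / (na * nb))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _angles_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ZeroVector("joint angle undefined for zero-length vector")
    c = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def joint_angle_series(poses: SegmentPose, model: BodyModel,
                       t: Optional[np.ndarray] = None,
                       rate: float = 1.0) -> JointAngleSeries:
    """The five flexion angles (BF, WF, SF, EF, KF) per frame, sides split.

    BF: chest vs waist.  WF: waist vs the mean thigh direction.  SF: upper arm
    vs chest (trunk-to-upper-arm reading of the adjacent-segment rule).
    EF: forearm vs upper arm.  KF: calf vs thigh.
    """
    v = {name: poses.segment_vector(name) for name in model.segments}
    thigh_mean = 0.5 * (v["thigh_l"] + v["thigh_r"])
    angles = {
        "BF": _angles_between(v["chest"], v["waist"]),
        "WF": _angles_between(v["waist"], thigh_mean),
        "SFl": _angles_between(v["chest"], v["upper_arm_l"]),
        "SFr": _angles_between(v["chest"], v["upper_arm_r"]),
        "EFl": _angles_between(v["upper_arm_l"], v["forearm_l"]),
        "EFr": _angles_between(v["upper_arm_r"], v["forearm_r"]),
        "KFl": _angles_between(v["thigh_l"], v["calf_l"]),
        "KFr": _angles_between(v["thigh_r"], v["calf_r"]),
    }
    tt = poses.t if t is None else np.asarray(t, dtype=float)
    return JointAngleSeries(tt, angles, rate)
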