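"""Forward kinematics and per-frame skeletal features.

World convention: right-handed, Z-up. Each joint's Euler rotation is
composed intrinsically in the joint's declared ``rotation_order``; the
world rotation of a joint is the product of its ancestors' local rotations
times its own, and a child's position is its parent's position plus the
parent-chain rotation applied to the child's offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .skeleton_io import MotionSequence, Skeleton

__all__ = [
    "PoseFeatureFrame",
    "BodyPartition",
    "forward_kinematics",
    "angular_velocity",
    "root_relative",
    "build_point_cloud",
    "unflatten_point_cloud",
    "partition_body",
    "pose_features",
    "DEFAULT_PART_RULES",
    "POINT_CLOUD_JOINTS",
    "POINT_CLOUD_DIM",
]

POINT_CLOUD_JOINTS = 32
POINT_CLOUD_DIM = 3 * POINT_CLOUD_JOINTS  # 96


@dataclass
class PoseFeatureFrame:
    """Features of one frame: root-relative positions, angular velocities
    (degrees/second, per channel) and the flat 96-dim point cloud."""

    positions: np.ndarray  # (J, 3) root-relative
    angular_velocity: np.ndarray  # (C,) deg/s; zeros where undefined
    point_cloud: np.ndarray  # (96,)

    def __post_init__(self) -> None:
        if self.point_cloud.shape != (POINT_CLOUD_DIM,):
            raise ValueError("point_cloud must have length 96")


@dataclass
class BodyPartition:
    """Total map from joint index to one of the five body parts."""

    part_map: dict[int, str]

    PARTS = ("trunk", "left_upper", "left_lower", "right_upper", "right_lower")

    def joints_in(self, part: str) -> list[int]:
        return [i for i, p in self.part_map.items() if p == part]


def _local_rotations(skeleton: Skeleton, frame: np.ndarray) -> list[Rotation]:
    rot_slices = skeleton.rotation_slices()
    rots = []
    for j, sl in zip(skeleton.joints, rot_slices):
        angles = np.zeros(3)
        angles[np.asarray(j.dof_mask, dtype=bool)] = frame[sl]
        # uppercase seq -> intrinsic composition in declared order
        rots.append(Rotation.from_euler(j.rotation_order, angles, degrees=True))
    return rots


def forward_kinematics(skeleton: Skeleton, frame: np.ndarray) -> np.ndarray:
    """World joint positions for one channel vector.

    Returns a ``(J, 3)`` array. The root lands at the frame's translation
    channels; every other joint at ``parent_position +
    R(ancestor chain incl. parent) @ offset``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (skeleton.n_channels,):
        raise ValueError(
            f"frame has {frame.shape} channels, skeleton expects {skeleton.n_channels}"
        )
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite channel values")
    local = _local_rotations(skeleton, frame)
    J = skeleton.n_joints
    positions = np.zeros((J, 3))
    world_rot: list[Rotation] = [None] * J  # type: ignore[list-item]
    positions[0] = frame[:3]
    world_rot[0] = local[0]
    for i in range(1, J):
        p = skeleton.joints[i].parent
        positions[i] = positions[p] + world_rot[p].apply(skeleton.joints[i].offset)
        world_rot[i] = world_rot[p] * local[i]
    return positions


def _wrap_degrees(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180]."""
    w = (delta + 180.0) % 360.0 - 180.0
    w[w == -180.0] = 180.0
    return w


def angular_velocity(
    motion: MotionSequence, interval: int = 1, wrap: bool = True
) -> np.ndarray:
    """First-difference channel velocities over a frame interval.

    ``v[t] = (theta[t+interval] - theta[t]) / (interval / frame_rate)`` in
    degrees/second; the rotation-channel differences are wrapped to
    (-180, 180] first so a 359->0 crossing reads as +1 degree, not -359.
    Translation channels are differenced unwrapped. Output has
    ``F - interval`` rows.
    """
    if interval < 1:
        raise ValueError("interval must be a positive integer")
    if interval >= motion.n_frames:
        raise ValueError("interval exceeds sequence length")
    delta = motion.frames[interval:] - motion.frames[:-interval]
    if wrap:
        delta = delta.copy()
        delta[:, 3:] = _wrap_degrees(delta[:, 3:])
    dt = interval / motion.frame_rate
    return delta / dt


def root_relative(positions: np.ndarray, reference: str = "root") -> np.ndarray:
    """Subtract a reference point (root joint row or the joint centroid)."""
    positions = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions contain non-finite values")
    if reference == "root":
        ref = positions[0]
    elif reference == "centroid":
        ref = positions.mean(axis=0)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return positions - ref


def build_point_cloud(positions: np.ndarray) -> np.ndarray:
    """Flatten root-relative positions into the 96-vector.

    The first 32 joints (skeleton order) are kept; fewer are zero-padded.
    Layout is channel-major: elements 0..31 are x of joints 0..31, 32..63
    are y, 64..95 are z.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] < 1:
        raise ValueError("positions must be a (J >= 1, 3) array")
    padded = np.zeros((POINT_CLOUD_JOINTS, 3))
    n = min(positions.shape[0], POINT_CLOUD_JOINTS)
    padded[:n] = positions[:n]
    return padded.T.reshape(POINT_CLOUD_DIM)


def unflatten_point_cloud(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`build_point_cloud`: 96-vector -> (32, 3) table."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (POINT_CLOUD_DIM,):
        raise ValueError("point cloud vector must have length 96")
    return vector.reshape(3, POINT_CLOUD_JOINTS).T


# Substring rules over canonical CMU/BVH joint names. First match wins;
# anything unmatched lands in the trunk.
DEFAULT_PART_RULES: dict[str, str] = {
    "lhipjoint": "left_lower",
    "lfemur": "left_lower",
    "ltibia": "left_lower",
    "lfoot": "left_lower",
    "ltoes": "left_lower",
    "lthigh": "left_lower",
    "lshin": "left_lower",
    "lankle": "left_lower",
    "rhipjoint": "right_lower",
    "rfemur": "right_lower",
    "rtibia": "right_lower",
    "rfoot": "right_lower",
    "rtoes": "right_lower",
    "rthigh": "right_lower",
    "rshin": "right_lower",
    "rankle": "right_lower",
    "lclavicle": "left_upper",
    "lhumerus": "left_upper",
    "lradius": "left_upper",
    "lwrist": "left_upper",
    "lhand": "left_upper",
    "lfingers": "left_upper",
    "lthumb": "left_upper",
    "lshoulder": "left_upper",
    "lelbow": "left_upper",
    "rclavicle": "right_upper",
    "rhumerus": "right_upper",
    "rradius": "right_upper",
    "rwrist": "right_upper",
    "rhand": "right_upper",
    "rfingers": "right_upper",
    "rthumb": "right_upper",
    "rshoulder": "right_upper",
    "relbow": "right_upper",
}


def partition_body(
    skeleton: Skeleton, name_rules: dict[str, str] | None = None
) -> BodyPartition:
    """Assign every joint to one of the five body parts by name rules.

    Rules are case-insensitive substring matches; the first matching rule
    (in rule order) wins and unmatched joints default to the trunk.
    """
    rules = DEFAULT_PART_RULES if name_rules is None else name_rules
    part_map: dict[int, str] = {}
    for i, joint in enumerate(skeleton.joints):
        lname = joint.name.lower()
        part = "trunk"
        for pattern, target in rules.items():
            if pattern.lower() in lname:
                if target not in BodyPartition.PARTS:
                    raise ValueError(f"rule {pattern!r} maps to unknown part {target!r}")
                part = target
                break
        part_map[i] = part
    return BodyPartition(part_map)


def pose_features(
    motion: MotionSequence,
    interval: int = 1,
    reference: str = "root",
) -> list[PoseFeatureFrame]:
    """Per-frame feature extraction for a whole sequence.

    Velocities for the last ``interval`` frames (which have no forward
    difference) are zero-filled so every frame yields a feature record.
    """
    vel = np.zeros_like(motion.frames)
    vel[: motion.n_frames - interval] = angular_velocity(motion, interval)
    out = []
    for t in range(motion.n_frames):
        pos = forward_kinematics(motion.skeleton, motion.frames[t])
        rel = root_relative(pos, reference)
        out.append(
            PoseFeatureFrame(
                positions=rel,
                angular_velocity=vel[t],
                point_cloud=build_point_cloud(rel),
            )
        )
    return out


def feature_matrix(features: list[PoseFeatureFrame]) -> np.ndarray:
    """Stack point clouds of a feature list into an (F, 96) array."""
    return np.stack([f.point_cloud for f in features])
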