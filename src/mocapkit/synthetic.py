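"""Ground-truth generators for every stage of the pipeline.

All generators are pure functions of their parameters and seed. The
styled motions are sinusoidal: each free joint channel oscillates as
``amplitude * sin(2*pi*f*t + phase)`` around the style's base frequency,
with the root advancing at constant speed and bouncing vertically, so
walking / running / jumping are separable in frequency-amplitude space
while still overlapping enough to exercise similarity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reconstruction import CameraModel, dlt_project
from .skeleton_io import Joint, MotionSequence, Skeleton

__all__ = [
    "StyleSpec",
    "STYLES",
    "gen_skeleton",
    "gen_motion",
    "motion_ground_truth",
    "gen_camera_rig",
    "pinhole_project",
    "gen_observations",
    "gen_two_system_waveforms",
    "expected_cmc",
]


@dataclass(frozen=True)
class StyleSpec:
    """A cyclic motion style: base frequency, channel amplitude scale,
    root kinematics and additive angle noise."""

    name: str
    base_frequency: float  # Hz
    amplitude_deg: float  # typical joint swing
    root_speed: float  # length units / second along +x
    bounce_amplitude: float  # vertical (z) bounce, length units
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.base_frequency > 0:
            raise ValueError("base_frequency must be positive")
        if not np.isfinite(self.amplitude_deg):
            raise ValueError("amplitude must be finite")


STYLES: dict[str, StyleSpec] = {
    "walking": StyleSpec("walking", base_frequency=1.0, amplitude_deg=25.0,
                         root_speed=1.2, bounce_amplitude=0.03),
    "running": StyleSpec("running", base_frequency=2.4, amplitude_deg=45.0,
                         root_speed=3.2, bounce_amplitude=0.08),
    "jumping": StyleSpec("jumping", base_frequency=0.8, amplitude_deg=60.0,
                         root_speed=0.3, bounce_amplitude=0.30),
}


# Humanoid template: trunk chain + four limbs, listed in depth-first
# order (the order BVH nesting imposes) so generated skeletons survive a
# write/read cycle without joint permutation. 32 joints fill the point
# cloud with no padding; lower-limb names follow the CMU convention so
# the default partition rules bite.
_TEMPLATE: list[tuple[str, str | None, tuple[float, float, float]]] = [
    ("root", None, (0.0, 0.0, 0.0)),
    ("lowerback", "root", (0.0, 0.0, 0.12)),
    ("upperback", "lowerback", (0.0, 0.0, 0.12)),
    ("thorax", "upperback", (0.0, 0.0, 0.12)),
    ("lowerneck", "thorax", (0.0, 0.0, 0.08)),
    ("upperneck", "lowerneck", (0.0, 0.0, 0.08)),
    ("head", "upperneck", (0.0, 0.0, 0.10)),
    ("headtop", "head", (0.0, 0.0, 0.08)),
    ("lclavicle", "thorax", (0.08, 0.0, 0.05)),
    ("lhumerus", "lclavicle", (0.14, 0.0, -0.02)),
    ("lradius", "lhumerus", (0.0, 0.0, -0.28)),
    ("lwrist", "lradius", (0.0, 0.0, -0.24)),
    ("lhand", "lwrist", (0.0, 0.0, -0.08)),
    ("lfingers", "lhand", (0.0, 0.0, -0.06)),
    ("lthumb", "lhand", (0.03, 0.0, -0.03)),
    ("rclavicle", "thorax", (-0.08, 0.0, 0.05)),
    ("rhumerus", "rclavicle", (-0.14, 0.0, -0.02)),
    ("rradius", "rhumerus", (0.0, 0.0, -0.28)),
    ("rwrist", "rradius", (0.0, 0.0, -0.24)),
    ("rhand", "rwrist", (0.0, 0.0, -0.08)),
    ("rfingers", "rhand", (0.0, 0.0, -0.06)),
    ("rthumb", "rhand", (0.03, 0.0, -0.03)),
    ("lhipjoint", "root", (0.10, 0.0, -0.05)),
    ("lfemur", "lhipjoint", (0.02, 0.0, -0.40)),
    ("ltibia", "lfemur", (0.0, 0.0, -0.40)),
    ("lfoot", "ltibia", (0.0, 0.10, -0.08)),
    ("ltoes", "lfoot", (0.0, 0.08, 0.0)),
    ("rhipjoint", "root", (-0.10, 0.0, -0.05)),
    ("rfemur", "rhipjoint", (-0.02, 0.0, -0.40)),
    ("rtibia", "rfemur", (0.0, 0.0, -0.40)),
    ("rfoot", "rtibia", (0.0, 0.10, -0.08)),
    ("rtoes", "rfoot", (0.0, 0.08, 0.0)),
]


def gen_skeleton(n_joints: int = 32, seed: int = 0) -> Skeleton:
    """Deterministic humanoid-like skeleton with ``n_joints`` joints.

    The first ``n_joints`` entries of the template are used (topological
    order, so any prefix is a valid hierarchy); beyond 32, extra spine
    segments are appended. Offsets get a small seeded jitter so distinct
    seeds produce distinct but equally shaped skeletons.
    """
    if n_joints < 2:
        raise ValueError("need at least 2 joints")
    rng = np.random.default_rng(seed)
    entries = list(_TEMPLATE[:n_joints])
    while len(entries) < n_joints:
        idx = len(entries) - len(_TEMPLATE)
        parent = "headtop" if idx == 0 else f"spine_extra{idx - 1}"
        entries.append((f"spine_extra{idx}", parent, (0.0, 0.0, 0.05)))
    name_to_index = {name: i for i, (name, _, _) in enumerate(entries)}
    joints = []
    for name, parent, offset in entries:
        jitter = 0.01 * rng.standard_normal(3) if parent is not None else np.zeros(3)
        joints.append(
            Joint(
                name=name,
                parent=None if parent is None else name_to_index[parent],
                offset=np.asarray(offset) + jitter,
                rotation_order="ZXY",
                dof_mask=(True, True, True),
            )
        )
    return Skeleton(joints)


def motion_ground_truth(
    skeleton: Skeleton,
    style: StyleSpec,
    n_frames: int,
    frame_rate: float,
    seed: int = 0,
) -> np.ndarray:
    """Noiseless channel table the generator is built on (the ground truth).

    The per-channel amplitudes and phases are drawn deterministically from
    the seed, so :func:`gen_motion` with the same arguments produces this
    table plus (optional) Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    C = skeleton.n_channels
    t = np.arange(n_frames) / frame_rate
    amps = style.amplitude_deg * (0.4 + 0.6 * rng.random(C - 3))
    phases = rng.uniform(0.0, 2.0 * np.pi, C - 3)
    frames = np.zeros((n_frames, C))
    frames[:, 0] = style.root_speed * t
    frames[:, 2] = style.bounce_amplitude * np.sin(
        2.0 * np.pi * 2.0 * style.base_frequency * t
    )
    frames[:, 3:] = amps[None, :] * np.sin(
        2.0 * np.pi * style.base_frequency * t[:, None] + phases[None, :]
    )
    return frames


def gen_motion(
    skeleton: Skeleton,
    style: StyleSpec,
    n_frames: int = 240,
    frame_rate: float = 60.0,
    seed: int = 0,
) -> MotionSequence:
    """Styled cyclic motion: sinusoidal channels plus Gaussian angle noise."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = motion_ground_truth(skeleton, style, n_frames, frame_rate, seed)
    if style.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))
        frames = frames.copy()
        frames[:, 3:] += style.noise_sd * noise_rng.standard_normal(
            frames[:, 3:].shape
        )
    return MotionSequence(skeleton, frame_rate, frames, name=style.name)


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------


def _look_at(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation with +z looking from position toward target."""
    forward = target - position
    forward = forward / np.linalg.norm(forward)
    up_hint = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(forward, up_hint)) > 0.99:
        up_hint = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up_hint)
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    return np.stack([right, down, forward])


def pinhole_project(
    position: np.ndarray,
    rotation: np.ndarray,
    focal: float,
    principal_point: tuple[float, float],
    point: np.ndarray,
) -> np.ndarray:
    """Independent pinhole projection oracle (no DLT parameterization)."""
    pc = rotation @ (np.asarray(point, dtype=float) - position)
    return np.array(
        [
            principal_point[0] + focal * pc[0] / pc[2],
            principal_point[1] + focal * pc[1] / pc[2],
        ]
    )


def gen_camera_rig(
    n_cameras: int = 8,
    distortion_spec: dict | None = None,
    seed: int = 0,
    radius: float = 4.0,
    focal: float = 1000.0,
    image_size: tuple[float, float] = (1280.0, 1024.0),
    elevation: float = 0.6,
    return_poses: bool = False,
):
    """Cameras on a circle around the origin, all looking at it.

    Each camera's L is derived from its pose and intrinsics through the
    projective relation, so the linear part of :func:`dlt_project`
    reproduces :func:`pinhole_project` exactly. ``distortion_spec`` (keys
    k1, k2, p1, p2) injects known distortion into every camera.
    """
    if n_cameras < 2:
        raise ValueError("need at least 2 cameras")
    rng = np.random.default_rng(seed)
    dist = distortion_spec or {}
    u0, v0 = image_size[0] / 2.0, image_size[1] / 2.0
    cameras = []
    poses = []
    for i in range(n_cameras):
        angle = 2.0 * np.pi * i / n_cameras + rng.uniform(-0.05, 0.05)
        z = elevation + rng.uniform(-0.1, 0.1)
        position = np.array(
            [radius * np.cos(angle), radius * np.sin(angle), z]
        )
        R = _look_at(position, np.zeros(3))
        K = np.array([[focal, 0.0, u0], [0.0, focal, v0], [0.0, 0.0, 1.0]])
        P = K @ np.hstack([R, (-R @ position)[:, None]])
        P = P / P[2, 3]  # denominator convention: ... + 1
        L = np.concatenate([P[0, :], P[1, :], P[2, :3]])
        cameras.append(
            CameraModel(
                L=L,
                k1=float(dist.get("k1", 0.0)),
                k2=float(dist.get("k2", 0.0)),
                p1=float(dist.get("p1", 0.0)),
                p2=float(dist.get("p2", 0.0)),
                principal_point=(u0, v0),
                image_size=image_size,
            )
        )
        poses.append({"position": position, "rotation": R, "focal": focal,
                      "principal_point": (u0, v0)})
    if return_poses:
        return cameras, poses
    return cameras


def gen_observations(
    rig: list[CameraModel],
    marker_trajectories: np.ndarray,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Project marker trajectories through every camera, with pixel noise.

    ``marker_trajectories`` has shape (p, f, 3). Returns the observation
    table (columns camera, frame, marker, u, v; c*f*p rows minus any
    degenerate projections) and the count of excluded degenerate rows.
    """
    traj = np.asarray(marker_trajectories, dtype=float)
    p, f, _ = traj.shape
    rng = np.random.default_rng(seed)
    rows = []
    excluded = 0
    for i, cam in enumerate(rig):
        for k in range(p):
            for j in range(f):
                try:
                    uv = dlt_project(cam, traj[k, j])
                except ValueError:
                    excluded += 1
                    continue
                if pixel_noise_sd > 0:
                    uv = uv + pixel_noise_sd * rng.standard_normal(2)
                rows.append(
                    {"camera": i, "frame": j, "marker": k, "u": uv[0], "v": uv[1]}
                )
    return pd.DataFrame(rows), excluded


# ---------------------------------------------------------------------------
# two-system waveforms
# ---------------------------------------------------------------------------


def gen_two_system_waveforms(
    signal: np.ndarray,
    offset: float = 0.0,
    noise_sd_a: float = 0.0,
    noise_sd_b: float = 0.0,
    n_trials: int = 3,
    seed: int = 0,
    joint: str = "knee",
    plane: str = "flexion_extension",
):
    """Paired recordings of one underlying curve by two systems.

    System A trials are ``signal + offset + noise_a``; system B trials are
    ``signal + noise_b``. The expected CMC of the pooled trials follows in
    closed form from the signal variance and noise variances (see
    :func:`expected_cmc`).
    """
    from .waveform_stats import JointAngleWaveform

    if n_trials < 2:
        raise ValueError("need at least 2 trials per system")
    signal = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    a = signal[None, :] + offset + noise_sd_a * rng.standard_normal(
        (n_trials, signal.size)
    )
    b = signal[None, :] + noise_sd_b * rng.standard_normal((n_trials, signal.size))
    wa = JointAngleWaveform(joint=joint, plane=plane, system="A", trials=a)
    wb = JointAngleWaveform(joint=joint, plane=plane, system="B", trials=b)
    return wa, wb


def expected_cmc(
    signal: np.ndarray,
    noise_sd_a: float,
    noise_sd_b: float,
    n_trials_a: int,
    n_trials_b: int,
) -> float:
    """Closed-form expectation of the between-system CMC for the generator.

    ``compare_systems`` takes the CMC between the two per-system *mean*
    curves, whose residual noise variances are sd^2 / T. For curves
    y_mt = s_t + e_mt with e_mt ~ N(0, v_m), the CMC variance ratio's
    numerator converges to the mean of the v_m and its denominator to
    Var(s) plus that mean, so
    ``CMC -> sqrt(Var(s) / (Var(s) + mean residual var))``. Assumes
    offsets are removed (align=True) or zero.
    """
    signal = np.asarray(signal, dtype=float)
    var_s = float(np.var(signal))
    mean_noise = 0.5 * (
        noise_sd_a**2 / n_trials_a + noise_sd_b**2 / n_trials_b
    )
    return float(np.sqrt(var_s / (var_s + mean_noise)))


def gait_signal(n_samples: int = 101, amplitude: float = 30.0) -> np.ndarray:
    """A smooth gait-like double-bump cycle used as the default signal."""
    t = np.linspace(0.0, 1.0, n_samples)
    return amplitude * (
        0.7 * np.sin(2.0 * np.pi * t - 0.3)
        + 0.3 * np.sin(4.0 * np.pi * t + 0.5)
    )
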