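import numpy as np
import pytest

from mocapkit import synthetic
from mocapkit.skeleton_io import Joint, MotionSequence, Skeleton


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_joint_skeleton():
    return Skeleton(
        [
            Joint("root", None, (0, 0, 0), "ZXY", (True, True, True)),
            Joint("child", 0, (1, 0, 0), "ZXY", (True, True, True)),
        ]
    )


@pytest.fixture
def zero_motion(two_joint_skeleton):
    return MotionSequence(
        two_joint_skeleton,
        60.0,
        np.zeros((10, two_joint_skeleton.n_channels)),
        name="zero",
    )


@pytest.fixture
def humanoid():
    return synthetic.gen_skeleton(32, seed=1)


@pytest.fixture
def walking(humanoid):
    return synthetic.gen_motion(
        humanoid, synthetic.STYLES["walking"], n_frames=120, frame_rate=60.0, seed=3
    )


def random_skeleton(rng, n_joints=10, dfs=True):
    """Random valid skeleton: random tree with parents preceding children."""
    from mocapkit.skeleton_io import dfs_order, reorder_joints

    joints = [Joint("root", None, np.zeros(3))]
    orders = ["XYZ", "ZXY", "YZX", "ZYX", "XZY", "YXZ"]
    for i in range(1, n_joints):
        parent = int(rng.integers(0, i))
        order = orders[int(rng.integers(0, len(orders)))]
        mask = tuple(bool(b) for b in rng.integers(0, 2, 3)) if rng.random() < 0.3 else (True, True, True)
        joints.append(Joint(f"j{i}", parent, rng.normal(size=3), order, mask))
    sk = Skeleton(joints)
    if dfs:
        sk, _ = reorder_joints(sk, None, dfs_order(sk))
    return sk
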