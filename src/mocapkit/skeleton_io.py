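"""Hierarchical skeleton and motion file IO (BVH and the CMU ASF/AMC dialect).

The internal data model is deliberately small: a :class:`Skeleton` is an
ordered list of joints (parents always precede children) and a
:class:`MotionSequence` is a dense ``(F, C)`` float table whose first three
columns are the root translation and whose remaining columns are per-joint
Euler angles in degrees, laid out joint by joint in skeleton order.

Angles are stored in degrees everywhere; conversion to radians happens
inside the kinematics routines only.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass
import numpy as np

__all__ = [
    "Joint",
    "Skeleton",
    "MotionSequence",
    "MotionParseError",
    "read_motion",
    "write_motion",
    "read_bvh",
    "write_bvh",
    "read_asf_amc",
    "dfs_order",
    "reorder_joints",
]

_AXES = "XYZ"


class MotionParseError(ValueError):
    """Raised when a motion file violates the dialect being parsed."""


@dataclass(frozen=True)
class Joint:
    """One joint of the hierarchy.

    ``rotation_order`` is the order rotation channels are applied
    (intrinsic composition, BVH convention). ``dof_mask`` marks which of
    those three channels are free; locked channels are held at zero and
    carry no column in the motion table.
    """

    name: str
    parent: int | None
    offset: np.ndarray
    rotation_order: str = "ZXY"
    dof_mask: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))
        if sorted(self.rotation_order) != ["X", "Y", "Z"]:
            raise ValueError(
                f"joint {self.name!r}: rotation_order {self.rotation_order!r} "
                "must be a permutation of XYZ"
            )
        if len(self.dof_mask) != 3:
            raise ValueError(f"joint {self.name!r}: dof_mask must have 3 entries")

    @property
    def n_dof(self) -> int:
        return int(sum(self.dof_mask))


@dataclass
class Skeleton:
    """Ordered joint hierarchy. Exactly one root; parents precede children."""

    joints: list[Joint]

    def __post_init__(self) -> None:
        roots = [i for i, j in enumerate(self.joints) if j.parent is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        if roots[0] != 0:
            raise ValueError("root joint must come first")
        for i, j in enumerate(self.joints[1:], start=1):
            if j.parent is None or not (0 <= j.parent < i):
                raise ValueError(
                    f"joint {j.name!r} (index {i}) has parent index {j.parent}; "
                    "parents must precede children"
                )

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def n_channels(self) -> int:
        """Total motion channels: 3 root translations + all free Euler DOFs."""
        return 3 + sum(j.n_dof for j in self.joints)

    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def rotation_slices(self) -> list[slice]:
        """Column slice of each joint's rotation channels in the frame vector."""
        out, start = [], 3
        for j in self.joints:
            out.append(slice(start, start + j.n_dof))
            start += j.n_dof
        return out

    def children(self, index: int) -> list[int]:
        return [i for i, j in enumerate(self.joints) if j.parent == index]


@dataclass
class MotionSequence:
    """Per-frame channel table bound to a skeleton.

    ``frames[t]`` is ``[tx, ty, tz, <joint 0 free angles>, <joint 1 ...>]``
    with angles in degrees.
    """

    skeleton: Skeleton
    frame_rate: float
    frames: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (F >= 1, C) table")
        if self.frames.shape[1] != self.skeleton.n_channels:
            raise ValueError(
                f"channel count mismatch: frames have {self.frames.shape[1]}, "
                f"skeleton expects {self.skeleton.n_channels}"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def copy(self) -> "MotionSequence":
        return MotionSequence(self.skeleton, self.frame_rate, self.frames.copy(), self.name)


# ---------------------------------------------------------------------------
# BVH
# ---------------------------------------------------------------------------

_POSITION_CHANNELS = {"Xposition": 0, "Yposition": 1, "Zposition": 2}
_ROTATION_CHANNELS = {"Xrotation": "X", "Yrotation": "Y", "Zrotation": "Z"}


def read_bvh(path: str | os.PathLike) -> tuple[Skeleton, MotionSequence]:
    with open(path, "r") as fh:  # newline=None: CRLF handled transparently
        text = fh.read()
    return _parse_bvh(text, name=os.path.splitext(os.path.basename(path))[0])


def _parse_bvh(text: str, name: str = "") -> tuple[Skeleton, MotionSequence]:
    tokens = text.split()
    pos = 0

    def peek() -> str:
        if pos >= len(tokens):
            raise MotionParseError("unexpected end of BVH file")
        return tokens[pos]

    def take(expected: str | None = None) -> str:
        nonlocal pos
        tok = peek()
        if expected is not None and tok.upper() != expected.upper():
            raise MotionParseError(f"expected {expected!r}, got {tok!r}")
        pos += 1
        return tok

    joints: list[Joint] = []
    # channel map: list of (joint_index, column_in_frame_vector_or_rotation_letter)
    channel_map: list[tuple[str, int, int]] = []  # (kind, joint, pos_axis_or_dof_slot)

    def parse_joint(parent: int | None) -> None:
        nonlocal pos
        kw = take()  # ROOT / JOINT
        jname = take()
        take("{")
        take("OFFSET")
        offset = np.array([float(take()) for _ in range(3)])
        take("CHANNELS")
        n_ch = int(take())
        chans = [take() for _ in range(n_ch)]
        rot_letters = [
            _ROTATION_CHANNELS[c] for c in chans if c in _ROTATION_CHANNELS
        ]
        if len(set(rot_letters)) != len(rot_letters):
            raise MotionParseError(f"joint {jname!r}: duplicate rotation channel")
        order = "".join(rot_letters) + "".join(a for a in _AXES if a not in rot_letters)
        mask = tuple(i < len(rot_letters) for i in range(3))
        jidx = len(joints)
        joints.append(Joint(jname, parent, offset, order, mask))
        dof_slot = 0
        for c in chans:
            if c in _POSITION_CHANNELS:
                if parent is not None:
                    # non-root position channels unsupported; treated as error
                    raise MotionParseError(
                        f"joint {jname!r}: position channels only allowed on root"
                    )
                channel_map.append(("pos", jidx, _POSITION_CHANNELS[c]))
            elif c in _ROTATION_CHANNELS:
                channel_map.append(("rot", jidx, dof_slot))
                dof_slot += 1
            else:
                raise MotionParseError(f"joint {jname!r}: unknown channel {c!r}")
        while True:
            tok = peek()
            if tok.upper() == "JOINT":
                parse_joint(jidx)
            elif tok.upper() == "END":  # End Site
                take()
                take()  # "Site"
                take("{")
                take("OFFSET")
                for _ in range(3):
                    take()
                take("}")
            elif tok == "}":
                take()
                return
            else:
                raise MotionParseError(f"unexpected token {tok!r} in joint {jname!r}")

    take("HIERARCHY")
    if peek().upper() != "ROOT":
        raise MotionParseError("BVH must start with a ROOT joint")
    parse_joint(None)
    skeleton = Skeleton(joints)

    take("MOTION")
    take("Frames:")
    n_frames = int(take())
    take("Frame")
    take("Time:")
    frame_time = float(take())
    if frame_time <= 0:
        raise MotionParseError("Frame Time must be positive")

    values = tokens[pos:]
    per_frame = len(channel_map)
    if len(values) != n_frames * per_frame:
        frame_idx = len(values) // per_frame if per_frame else 0
        raise MotionParseError(
            f"channel-count mismatch in MOTION section near frame {frame_idx}: "
            f"expected {n_frames * per_frame} values, got {len(values)}"
        )
    raw = np.array(values, dtype=float).reshape(n_frames, per_frame)

    frames = np.zeros((n_frames, skeleton.n_channels))
    rot_slices = skeleton.rotation_slices()
    for col, (kind, jidx, slot) in enumerate(channel_map):
        if kind == "pos":
            frames[:, slot] = raw[:, col]
        else:
            frames[:, rot_slices[jidx].start + slot] = raw[:, col]
    motion = MotionSequence(skeleton, 1.0 / frame_time, frames, name=name)
    return skeleton, motion


def dfs_order(skeleton: Skeleton) -> list[int]:
    """Depth-first joint visitation order (children kept in file order).

    BVH nesting forces this order on any written file, so the writer
    canonicalizes to it; a skeleton read back from BVH is always already
    DFS-ordered and round-trips without permutation.
    """
    children: dict[int, list[int]] = {i: [] for i in range(skeleton.n_joints)}
    for i, j in enumerate(skeleton.joints):
        if j.parent is not None:
            children[j.parent].append(i)
    order: list[int] = []
    stack = [0]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    return order


def reorder_joints(
    skeleton: Skeleton, motion: MotionSequence | None, order: list[int]
) -> tuple[Skeleton, MotionSequence | None]:
    """Permute joints (and the motion channel columns) to ``order``."""
    new_index = {old: new for new, old in enumerate(order)}
    joints = []
    for old in order:
        j = skeleton.joints[old]
        parent = None if j.parent is None else new_index[j.parent]
        joints.append(Joint(j.name, parent, j.offset, j.rotation_order, j.dof_mask))
    new_sk = Skeleton(joints)
    if motion is None:
        return new_sk, None
    old_slices = skeleton.rotation_slices()
    cols = [0, 1, 2]
    for old in order:
        cols.extend(range(old_slices[old].start, old_slices[old].stop))
    new_motion = MotionSequence(
        new_sk, motion.frame_rate, motion.frames[:, cols], name=motion.name
    )
    return new_sk, new_motion


def write_bvh(skeleton: Skeleton, motion: MotionSequence, path: str | os.PathLike) -> None:
    if motion.skeleton.n_channels != skeleton.n_channels or [
        j.name for j in motion.skeleton.joints
    ] != [j.name for j in skeleton.joints]:
        raise ValueError("motion does not match skeleton")
    order = dfs_order(skeleton)
    if order != list(range(skeleton.n_joints)):
        skeleton, motion = reorder_joints(skeleton, motion, order)  # type: ignore[assignment]
    buf = io.StringIO()
    rot_slices = skeleton.rotation_slices()
    channel_cols: list[int] = []

    def emit_joint(idx: int, depth: int) -> None:
        j = skeleton.joints[idx]
        ind = "  " * depth
        kw = "ROOT" if j.parent is None else "JOINT"
        buf.write(f"{ind}{kw} {j.name}\n{ind}{{\n")
        buf.write(
            f"{ind}  OFFSET {j.offset[0]:.6f} {j.offset[1]:.6f} {j.offset[2]:.6f}\n"
        )
        chans = []
        if j.parent is None:
            chans += ["Xposition", "Yposition", "Zposition"]
        free = [a for a, m in zip(j.rotation_order, j.dof_mask) if m]
        chans += [f"{a}rotation" for a in free]
        buf.write(f"{ind}  CHANNELS {len(chans)} {' '.join(chans)}\n")
        if j.parent is None:
            channel_cols.extend([0, 1, 2])
        channel_cols.extend(range(rot_slices[idx].start, rot_slices[idx].stop))
        kids = skeleton.children(idx)
        if not kids:
            buf.write(f"{ind}  End Site\n{ind}  {{\n{ind}    OFFSET 0.000000 0.000000 0.000000\n{ind}  }}\n")
        for k in kids:
            emit_joint(k, depth + 1)
        buf.write(f"{ind}}}\n")

    buf.write("HIERARCHY\n")
    emit_joint(0, 0)
    buf.write("MOTION\n")
    buf.write(f"Frames: {motion.n_frames}\n")
    buf.write(f"Frame Time: {1.0 / motion.frame_rate:.10f}\n")
    table = motion.frames[:, channel_cols]
    for row in table:
        buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# ASF / AMC (CMU dialect)
# ---------------------------------------------------------------------------


def _asf_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        line = line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.lstrip().startswith(":"):
            key = line.strip().split()[0][1:].lower()
            current = sections.setdefault(key, [])
            rest = line.strip()[len(key) + 1 :].strip()
            if rest:
                current.append(rest)
        elif current is not None:
            current.append(line.strip())
    return sections


def read_asf_amc(
    asf_path: str | os.PathLike,
    amc_path: str | os.PathLike,
    frame_rate: float = 120.0,
) -> tuple[Skeleton, MotionSequence]:
    """Parse a CMU-dialect ASF skeleton plus an AMC motion file.

    Angles must be in degrees (the ``:units`` block's ``angle deg`` and the
    AMC ``:DEGREES`` flag). ``axis`` frames, ``limits`` and documentation
    blocks are parsed but ignored; each bone's offset is ``direction *
    length`` and its rotation order is the listed ``dof`` order. AMC files
    carry no frame rate; the CMU capture rate of 120 fps is assumed unless
    overridden.
    """
    with open(asf_path, "r") as fh:
        sections = _asf_sections(fh.read())

    # --- root block
    root_order = ["TX", "TY", "TZ", "RX", "RY", "RZ"]
    root_axis = "XYZ"
    for line in sections.get("root", []):
        parts = line.split()
        if parts[0].lower() == "order":
            root_order = [p.upper() for p in parts[1:]]
        elif parts[0].lower() == "axis":
            root_axis = parts[1].upper()
    root_rot_letters = [o[1] for o in root_order if o.startswith("R")]
    root_rot_order = "".join(root_rot_letters) + "".join(
        a for a in _AXES if a not in root_rot_letters
    )
    root_mask = tuple(i < len(root_rot_letters) for i in range(3))

    # --- bonedata blocks
    bones: dict[str, dict] = {}
    bone_order: list[str] = []
    block: dict | None = None
    for line in sections.get("bonedata", []):
        parts = line.split()
        kw = parts[0].lower()
        if kw == "begin":
            block = {"dof": [], "direction": np.zeros(3), "length": 0.0}
        elif kw == "end":
            if block is None or "name" not in block:
                raise MotionParseError("bonedata block without a name")
            bones[block["name"]] = block
            bone_order.append(block["name"])
            block = None
        elif block is not None:
            if kw == "name":
                block["name"] = parts[1]
            elif kw == "direction":
                block["direction"] = np.array([float(x) for x in parts[1:4]])
            elif kw == "length":
                block["length"] = float(parts[1])
            elif kw == "dof":
                block["dof"] = [p.lower() for p in parts[1:]]
            # id, axis, limits: ignored

    # --- hierarchy
    parent_of: dict[str, str] = {}
    order_seen: list[str] = ["root"]
    for line in sections.get("hierarchy", []):
        parts = line.split()
        if parts[0].lower() in ("begin", "end"):
            continue
        parent = parts[0]
        if parent != "root" and parent not in bones:
            raise MotionParseError(f"hierarchy references unknown joint {parent!r}")
        for child in parts[1:]:
            if child not in bones:
                raise MotionParseError(f"hierarchy references unknown joint {child!r}")
            if child in parent_of or child == "root":
                raise MotionParseError(f"joint {child!r} appears twice in hierarchy")
            parent_of[child] = parent
            order_seen.append(child)

    # verify acyclic / connected: every listed child's ancestry terminates at root
    for child in parent_of:
        seen, cur = set(), child
        while cur != "root":
            if cur in seen:
                raise MotionParseError(f"hierarchy cycle involving joint {cur!r}")
            seen.add(cur)
            if cur not in parent_of:
                raise MotionParseError(f"joint {cur!r} is not connected to the root")
            cur = parent_of[cur]

    joints = [Joint("root", None, np.zeros(3), root_rot_order, root_mask)]
    index_of = {"root": 0}
    for bname in order_seen[1:]:
        b = bones[bname]
        dof_letters = [d[1].upper() for d in b["dof"] if d.startswith("r")]
        order = "".join(dof_letters) + "".join(a for a in _AXES if a not in dof_letters)
        mask = tuple(i < len(dof_letters) for i in range(3))
        joints.append(
            Joint(
                bname,
                index_of[parent_of[bname]],
                b["direction"] * b["length"],
                order,
                mask,
            )
        )
        index_of[bname] = len(joints) - 1
    skeleton = Skeleton(joints)

    # --- AMC
    with open(amc_path, "r") as fh:
        amc_lines = [
            ln.strip()
            for ln in fh.read().splitlines()
            if ln.strip() and not ln.strip().startswith("#") and not ln.strip().startswith(":")
        ]
    frames_raw: list[dict[str, list[float]]] = []
    current_frame: dict[str, list[float]] | None = None
    for ln in amc_lines:
        if re.fullmatch(r"\d+", ln):
            current_frame = {}
            frames_raw.append(current_frame)
        else:
            if current_frame is None:
                raise MotionParseError("AMC data before the first frame number")
            parts = ln.split()
            current_frame[parts[0]] = [float(x) for x in parts[1:]]
    if not frames_raw:
        raise MotionParseError("AMC file contains no frames")

    rot_slices = skeleton.rotation_slices()
    frames = np.zeros((len(frames_raw), skeleton.n_channels))
    for fidx, fr in enumerate(frames_raw):
        if "root" not in fr:
            raise MotionParseError(f"frame {fidx}: missing root channels")
        rv = fr["root"]
        if len(rv) != len(root_order):
            raise MotionParseError(
                f"frame {fidx}: root has {len(rv)} values, expected {len(root_order)}"
            )
        rslot = 0
        for val, chan in zip(rv, root_order):
            if chan.startswith("T"):
                frames[fidx, "XYZ".index(chan[1])] = val
            else:
                frames[fidx, rot_slices[0].start + rslot] = val
                rslot += 1
        for jidx, j in enumerate(skeleton.joints[1:], start=1):
            vals = fr.get(j.name, [])
            if len(vals) != j.n_dof:
                raise MotionParseError(
                    f"frame {fidx}: joint {j.name!r} has {len(vals)} values, "
                    f"expected {j.n_dof}"
                )
            frames[fidx, rot_slices[jidx]] = vals
    motion = MotionSequence(
        skeleton,
        frame_rate,
        frames,
        name=os.path.splitext(os.path.basename(str(amc_path)))[0],
    )
    return skeleton, motion


# ---------------------------------------------------------------------------
# front door
# ---------------------------------------------------------------------------


def read_motion(
    path: str | os.PathLike,
    format: str = "bvh",
    amc_path: str | os.PathLike | None = None,
) -> tuple[Skeleton, MotionSequence]:
    """Read a motion file. ``format`` is ``"bvh"`` or ``"asf_amc"``.

    For ``asf_amc``, ``path`` is the ASF skeleton and ``amc_path`` the AMC
    motion file.
    """
    if format == "bvh":
        return read_bvh(path)
    if format == "asf_amc":
        if amc_path is None:
            raise ValueError("asf_amc format requires amc_path")
        return read_asf_amc(path, amc_path)
    raise ValueError(f"unknown format {format!r}")


def write_motion(
    skeleton: Skeleton,
    motion: MotionSequence,
    path: str | os.PathLike,
    format: str = "bvh",
) -> None:
    """Write a motion file (BVH only)."""
    if format != "bvh":
        raise ValueError(f"unsupported output format {format!r}")
    write_bvh(skeleton, motion, path)
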