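"""Motion graph construction, transition selection and blended synthesis.

Graph vertices are (sequence id, frame) pairs. Temporal edges chain the
frames of each source sequence with similarity 1; each candidate
similar-frame pair contributes a directed transition edge in both
directions with similarity ``1 / (1 + distance)``. Frames linked by
candidate pairs share a ``group`` attribute (connected components of the
candidate relation) — the "similar posture" node groups.

Transition paths maximize the bottleneck (minimum) edge similarity; ties
prefer fewer transition edges, then the earliest source frame. Synthesis
splices sequences with a linear blend window: root translation is
interpolated linearly and joint rotations by quaternion slerp, and the
target sequence is rigidly translated so roots stay continuous across
the splice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .skeleton_io import MotionSequence

__all__ = [
    "MotionGraph",
    "TransitionConfig",
    "TransitionPath",
    "build_graph",
    "select_transition",
    "blend_transition",
    "synthesize",
]


@dataclass(frozen=True)
class TransitionConfig:
    """Blend settings: window length (frames) and interpolation modes."""

    window: int = 30
    root_blend: str = "linear"
    rotation_blend: str = "slerp"

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("blend window must be at least 2 frames")
        if self.root_blend != "linear":
            raise ValueError(f"unknown root_blend {self.root_blend!r}")
        if self.rotation_blend not in ("slerp", "lerp_angles"):
            raise ValueError(f"unknown rotation_blend {self.rotation_blend!r}")


@dataclass
class MotionGraph:
    """Directed frame graph plus the frame counts of its source sequences."""

    graph: nx.DiGraph
    sequence_frames: dict[str, int]

    def transition_edges(self) -> list[tuple]:
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d["kind"] == "transition"
        ]


@dataclass
class TransitionPath:
    """Result of transition selection; ``found`` is False when no path exists."""

    found: bool
    edges: list[tuple]  # (u, v, attrs) along the path
    bottleneck: float | None = None
    reason: str | None = None

    def transition_steps(self) -> list[tuple]:
        return [e for e in self.edges if e[2]["kind"] == "transition"]


def similarity_from_distance(distance: float) -> float:
    """Map a non-negative embedding distance to a similarity in (0, 1]."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + distance)


def build_graph(
    sequences: Mapping[str, MotionSequence],
    candidates: Sequence[tuple[str, int, str, int, float]],
) -> MotionGraph:
    """Assemble the motion graph from sequences and candidate frame pairs.

    ``candidates`` rows are (seqA, frameA, seqB, frameB, distance). Frames
    out of range raise with the offending candidate named.
    """
    g = nx.DiGraph()
    frames = {name: seq.n_frames for name, seq in sequences.items()}
    for name, seq in sequences.items():
        for t in range(seq.n_frames):
            g.add_node((name, t))
        for t in range(seq.n_frames - 1):
            g.add_edge((name, t), (name, t + 1), kind="temporal", similarity=1.0)

    undirected = nx.Graph()
    for cand in candidates:
        sa, fa, sb, fb, dist = cand
        for s, f in ((sa, fa), (sb, fb)):
            if s not in frames:
                raise ValueError(f"candidate {cand!r}: unknown sequence {s!r}")
            if not (0 <= f < frames[s]):
                raise ValueError(f"candidate {cand!r}: frame {f} out of range for {s!r}")
        sim = similarity_from_distance(dist)
        g.add_edge((sa, fa), (sb, fb), kind="transition", similarity=sim, distance=dist)
        g.add_edge((sb, fb), (sa, fa), kind="transition", similarity=sim, distance=dist)
        undirected.add_edge((sa, fa), (sb, fb))

    # similar-posture groups: connected components of the candidate relation
    group = 0
    for comp in nx.connected_components(undirected):
        for node in comp:
            g.nodes[node]["group"] = group
        group += 1
    for node in g.nodes:
        g.nodes[node].setdefault("group", None)
    return MotionGraph(graph=g, sequence_frames=frames)


def select_transition(
    graph: MotionGraph, from_style: str, to_style: str
) -> TransitionPath:
    """Pick the path from ``from_style`` to ``to_style`` with the best
    bottleneck similarity; among equals, the one crossing the fewest
    transition edges, starting at the earliest source frame."""
    for style in (from_style, to_style):
        if style not in graph.sequence_frames:
            raise ValueError(f"sequence {style!r} not present in graph")
    if from_style == to_style:
        return TransitionPath(found=True, edges=[], bottleneck=1.0)

    g = graph.graph
    sims = sorted(
        {d["similarity"] for _, _, d in g.edges(data=True) if d["kind"] == "transition"},
        reverse=True,
    )
    targets = {n for n in g.nodes if n[0] == to_style}
    sources = [(from_style, t) for t in range(graph.sequence_frames[from_style])]

    def subgraph_at(bottleneck: float) -> nx.DiGraph:
        return g.edge_subgraph(
            (u, v)
            for u, v, d in g.edges(data=True)
            if d["similarity"] >= bottleneck - 1e-15
        )

    best_b = None
    for bottleneck in sims:  # descending: first reachable level is optimal
        sub = subgraph_at(bottleneck)
        present = [s for s in sources if s in sub]
        frontier = list(present)
        seen = set(present)
        hit = False
        while frontier and not hit:
            nxt = []
            for n in frontier:
                for m in sub.successors(n):
                    if m not in seen:
                        seen.add(m)
                        nxt.append(m)
                        if m in targets:
                            hit = True
            frontier = nxt
        if hit:
            best_b = bottleneck
            break
    if best_b is None:
        return TransitionPath(found=False, edges=[], reason="no transition available")

    # Deterministic tie-breaking via one Dijkstra from a virtual source:
    # cost = 1e12 per transition edge + 1e6 per temporal step + the source
    # frame index, so the lexicographic order is (transition count, path
    # length, earliest source frame).
    sub = nx.DiGraph(subgraph_at(best_b))
    VS = ("__virtual__", -1)
    for s in sources:
        if s in sub or g.has_node(s):
            sub.add_edge(VS, s, kind="virtual", similarity=1.0, frame=s[1])

    def weight(u, v, d):
        if d["kind"] == "virtual":
            return float(d["frame"])
        return 1e12 if d["kind"] == "transition" else 1e6

    lengths, paths = nx.single_source_dijkstra(sub, VS, weight=weight)
    reach = [(lengths[t], t[1], t) for t in targets if t in lengths]
    if not reach:  # pragma: no cover - reachability established above
        return TransitionPath(found=False, edges=[], reason="no transition available")
    _, _, best_target = min(reach)
    nodes = paths[best_target][1:]  # drop virtual source
    edges = [(u, v, dict(g.edges[u, v])) for u, v in zip(nodes[:-1], nodes[1:])]
    return TransitionPath(found=True, edges=edges, bottleneck=best_b)


def _frame_rotations(seq: MotionSequence, frame_idx: int) -> list[Rotation]:
    sk = seq.skeleton
    rots = []
    for j, sl in zip(sk.joints, sk.rotation_slices()):
        angles = np.zeros(3)
        angles[np.asarray(j.dof_mask, dtype=bool)] = seq.frames[frame_idx, sl]
        rots.append(Rotation.from_euler(j.rotation_order, angles, degrees=True))
    return rots


def _rotations_to_channels(seq_skeleton, rotations: list[Rotation]) -> np.ndarray:
    out = np.zeros(seq_skeleton.n_channels)
    for (j, sl), rot in zip(
        zip(seq_skeleton.joints, seq_skeleton.rotation_slices()), rotations
    ):
        angles = rot.as_euler(j.rotation_order, degrees=True)
        out[sl] = angles[np.asarray(j.dof_mask, dtype=bool)]
    return out


def _segment(seq: MotionSequence, start: int, length: int, forward: bool) -> np.ndarray:
    """Frames [start, start+length) (forward) or (start-length, start]
    (backward), clamped by repeating the boundary frame."""
    idx = np.arange(length) + start if forward else np.arange(length) + start - length + 1
    idx = np.clip(idx, 0, seq.n_frames - 1)
    return seq.frames[idx]


def blend_transition(
    source: MotionSequence,
    target: MotionSequence,
    config: TransitionConfig = TransitionConfig(),
) -> MotionSequence:
    """Linear blend of two same-skeleton segments over the config window.

    Frame i uses weight ``w_i = i / (W - 1)``: the root translation is the
    linear mix and each joint rotation the slerp (or naive Euler lerp)
    between the segments' frame-i poses. Frame 0 is the source frame
    verbatim; frame W-1 the target frame verbatim.
    """
    if source.skeleton.joint_names() != target.skeleton.joint_names():
        raise ValueError("segments use different skeletons")
    if source.frame_rate != target.frame_rate:
        raise ValueError("frame-rate mismatch between segments")
    W = config.window
    src = _segment(source, 0, W, forward=True)
    tgt = _segment(target, target.n_frames - 1, W, forward=False)
    sk = source.skeleton
    out = np.empty((W, sk.n_channels))
    src_seq = MotionSequence(sk, source.frame_rate, src)
    tgt_seq = MotionSequence(sk, source.frame_rate, tgt)
    for i in range(W):
        w = i / (W - 1)
        if i == 0:
            out[i] = src[0]
            continue
        if i == W - 1:
            out[i] = tgt[W - 1]
            continue
        row = np.empty(sk.n_channels)
        row[:3] = (1.0 - w) * src[i, :3] + w * tgt[i, :3]
        if config.rotation_blend == "lerp_angles":
            row[3:] = (1.0 - w) * src[i, 3:] + w * tgt[i, 3:]
        else:
            rs = _frame_rotations(src_seq, i)
            rt = _frame_rotations(tgt_seq, i)
            blended = [
                Slerp([0.0, 1.0], Rotation.concatenate([a, b]))(w)
                for a, b in zip(rs, rt)
            ]
            row[3:] = _rotations_to_channels(sk, blended)[3:]
        out[i] = row
    return MotionSequence(sk, source.frame_rate, out, name="blend")


def synthesize(
    graph: MotionGraph,
    path: TransitionPath,
    sequences: Mapping[str, MotionSequence],
    config: TransitionConfig = TransitionConfig(),
) -> MotionSequence:
    """Render a path through the graph into one continuous sequence.

    For each transition edge ((sA, fA) -> (sB, fB)) the output carries sA's
    frames up to fA, a W-frame blend from sA@fA into sB@fB, then continues
    in sB after fB. Joint rotations blend per :func:`blend_transition`; the
    root path through the window integrates the linearly blended per-frame
    root steps of the two inputs (a convex combination at every frame, so
    the output root never jumps more than either input does), and the
    target sequence is rigidly translated to meet the integrated endpoint.
    Input sequences are never mutated.
    """
    for u, v, d in path.edges:
        if not graph.graph.has_edge(u, v):
            raise ValueError(f"path edge {u} -> {v} not present in graph")
    if not path.found:
        raise ValueError("cannot synthesize: no transition available")

    steps = path.transition_steps()
    if not steps:
        name = path.edges[0][0][0] if path.edges else next(iter(sequences))
        return sequences[name].copy()

    rate = {seq.frame_rate for seq in sequences.values()}
    if len(rate) > 1:
        raise ValueError("frame-rate mismatch between sequences")

    W = config.window
    first_seq = steps[0][0][0]
    current = sequences[first_seq].copy()
    cursor = 0  # next frame of `current` not yet emitted
    out_parts: list[np.ndarray] = []
    for (sa, fa), (sb, fb), d in steps:
        target = sequences[sb].copy()
        src_seg = _segment(current, fa, W, forward=True)
        tgt_seg = _segment(target, fb, W, forward=False)
        # velocity-blended root path through the window
        root = np.empty((W, 3))
        root[0] = src_seg[0, :3]
        for i in range(1, W):
            w = i / (W - 1)
            step = (1.0 - w) * (src_seg[i, :3] - src_seg[i - 1, :3]) + w * (
                tgt_seg[i, :3] - tgt_seg[i - 1, :3]
            )
            root[i] = root[i - 1] + step
        # rigid alignment: target meets the integrated root at the splice
        offset = root[-1] - target.frames[fb, :3]
        target.frames[:, :3] += offset
        out_parts.append(current.frames[cursor:fa])
        blend = blend_transition(
            MotionSequence(current.skeleton, current.frame_rate, src_seg),
            MotionSequence(target.skeleton, target.frame_rate,
                           _segment(target, fb, W, forward=False)),
            config,
        )
        blend.frames[:, :3] = root
        out_parts.append(blend.frames)
        current = target
        cursor = fb + 1
    out_parts.append(current.frames[cursor:])
    frames = np.concatenate(out_parts, axis=0)
    first = sequences[first_seq]
    return MotionSequence(
        first.skeleton,
        first.frame_rate,
        frames,
        name=f"{first_seq}_to_{steps[-1][1][0]}",
    )
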