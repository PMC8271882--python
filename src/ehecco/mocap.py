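"""BVH motion-capture I/O, forward kinematics and pose normalization.

BVH (Biovision Hierarchy) is a plain-text format with two sections: a
HIERARCHY describing a joint tree (per-joint 3-vector offset in the file's
length units plus an ordered channel list) and a MOTION section holding one
row of channel values per frame (positions in file units, rotations in
degrees). Forward kinematics composes, down the tree, each joint's local
transform — offset translation, then the channels in their declared order,
rotations intrinsic — to produce world-space joint positions.

Pose preprocessing for the recognition pipeline is *hip-based
normalization*: the root (hip) position is subtracted from every joint per
frame, removing global translation while keeping limb geometry and body
size (size must survive for the anthropometric correlation analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import BVHParseError, DimensionMismatchError

POSITION_CHANNELS = ("Xposition", "Yposition", "Zposition")
ROTATION_CHANNELS = ("Xrotation", "Yrotation", "Zrotation")
ALLOWED_CHANNELS = POSITION_CHANNELS + ROTATION_CHANNELS


@dataclass
class Joint:
    """One node of the skeleton tree; ``is_end_site`` nodes carry no channels."""

    name: str
    offset: np.ndarray
    channels: tuple[str, ...] = ()
    children: list["Joint"] = field(default_factory=list)
    is_end_site: bool = False

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.offset)):
            raise ValueError(f"joint {self.name!r} has a non-finite offset")
        for ch in self.channels:
            if ch not in ALLOWED_CHANNELS:
                raise ValueError(f"joint {self.name!r}: unknown channel {ch!r}")


@dataclass
class SkeletonHierarchy:
    """Joint tree with a single root; End Sites are kept as zero-channel leaves."""

    root: Joint

    def __post_init__(self):
        names = [j.name for j in self.joints()]
        if len(set(names)) != len(names):
            raise ValueError("joint names must be unique")

    def joints(self, include_end_sites: bool = False) -> list[Joint]:
        """Depth-first joint list in channel order."""
        out: list[Joint] = []

        def visit(j: Joint):
            if j.is_end_site and not include_end_sites:
                pass
            else:
                out.append(j)
            for c in j.children:
                visit(c)

        visit(self.root)
        return out

    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints()]

    def parents(self) -> dict[str, str | None]:
        par: dict[str, str | None] = {self.root.name: None}

        def visit(j: Joint):
            for c in j.children:
                par[c.name] = j.name
                visit(c)

        visit(self.root)
        return par

    @property
    def n_channels(self) -> int:
        return sum(len(j.channels) for j in self.joints(include_end_sites=True))


@dataclass
class MotionSequence:
    """Per-frame channel values paired with a hierarchy."""

    frame_time: float
    channel_values: np.ndarray

    def __post_init__(self):
        self.channel_values = np.atleast_2d(np.asarray(self.channel_values, dtype=float))
        if self.channel_values.shape[0] < 1:
            raise ValueError("motion must have at least one frame")
        if self.frame_time <= 0:
            raise ValueError(f"frame_time must be positive, got {self.frame_time}")

    @property
    def n_frames(self) -> int:
        return self.channel_values.shape[0]


@dataclass
class PoseSequence:
    """World-space joint positions over time: positions[t, j] is a 3-vector."""

    positions: np.ndarray
    joint_names: list[str]
    frame_time: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(f"positions must have shape (T, J, 3), got {self.positions.shape}")
        if self.positions.shape[1] != len(self.joint_names):
            raise DimensionMismatchError(
                "joint_names vs positions", len(self.joint_names), self.positions.shape[1]
            )
        if self.positions.shape[1] < 2:
            raise ValueError("a pose sequence needs at least 2 joints")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]


# ---------------------------------------------------------------------------
# parsing


class _Tokens:
    """Line-aware token stream over BVH text."""

    def __init__(self, text: str):
        self.items: list[tuple[str, int]] = []
        for ln, line in enumerate(text.splitlines(), start=1):
            for tok in line.split():
                self.items.append((tok, ln))
        self.pos = 0

    def peek(self) -> tuple[str, int]:
        if self.pos >= len(self.items):
            raise BVHParseError("unexpected end of file")
        return self.items[self.pos]

    def next(self, expect: str | None = None) -> tuple[str, int]:
        tok, ln = self.peek()
        self.pos += 1
        if expect is not None and tok.upper() != expect.upper():
            raise BVHParseError(f"expected {expect!r}, got {tok!r}", ln)
        return tok, ln

    def next_float(self) -> float:
        tok, ln = self.next()
        try:
            return float(tok)
        except ValueError:
            raise BVHParseError(f"expected a number, got {tok!r}", ln) from None

    def next_int(self) -> int:
        tok, ln = self.next()
        try:
            return int(tok)
        except ValueError:
            raise BVHParseError(f"expected an integer, got {tok!r}", ln) from None

    def done(self) -> bool:
        return self.pos >= len(self.items)


def _parse_joint(toks: _Tokens, name: str, end_counter: list[int]) -> Joint:
    toks.next("{")
    toks.next("OFFSET")
    offset = [toks.next_float() for _ in range(3)]
    channels: tuple[str, ...] = ()
    children: list[Joint] = []
    while True:
        tok, ln = toks.peek()
        up = tok.upper()
        if up == "CHANNELS":
            toks.next()
            n = toks.next_int()
            chs = []
            for _ in range(n):
                ch, chln = toks.next()
                if ch not in ALLOWED_CHANNELS:
                    raise BVHParseError(f"unknown channel name {ch!r}", chln)
                chs.append(ch)
            channels = tuple(chs)
        elif up == "JOINT":
            toks.next()
            child_name, _ = toks.next()
            children.append(_parse_joint(toks, child_name, end_counter))
        elif up == "END":
            toks.next()
            site, sln = toks.next()
            if site.upper() != "SITE":
                raise BVHParseError(f"expected 'Site' after 'End', got {site!r}", sln)
            toks.next("{")
            toks.next("OFFSET")
            off = [toks.next_float() for _ in range(3)]
            toks.next("}")
            end_counter[0] += 1
            children.append(
                Joint(name=f"__end_site_{end_counter[0]}", offset=off, is_end_site=True)
            )
        elif up == "}":
            toks.next()
            break
        else:
            raise BVHParseError(f"unexpected token {tok!r} in joint block", ln)
    return Joint(name=name, offset=offset, channels=channels, children=children)


def parse_bvh(text: str) -> tuple[SkeletonHierarchy, MotionSequence]:
    """Parse BVH text into a hierarchy and motion pair."""
    toks = _Tokens(text)
    toks.next("HIERARCHY")
    toks.next("ROOT")
    root_name, _ = toks.next()
    end_counter = [0]
    root = _parse_joint(toks, root_name, end_counter)
    hierarchy = SkeletonHierarchy(root=root)

    tok, ln = toks.next()
    if tok.upper() != "MOTION":
        raise BVHParseError(f"expected MOTION section, got {tok!r}", ln)
    frames_kw, ln = toks.next()
    if frames_kw.rstrip(":").upper() != "FRAMES":
        raise BVHParseError(f"expected 'Frames:', got {frames_kw!r}", ln)
    if not frames_kw.endswith(":"):
        toks.next(":")
    n_frames = toks.next_int()
    frame_kw, ln = toks.next()
    if frame_kw.upper() != "FRAME":
        raise BVHParseError(f"expected 'Frame Time:', got {frame_kw!r}", ln)
    time_kw, ln = toks.next()
    if time_kw.rstrip(":").upper() != "TIME":
        raise BVHParseError(f"expected 'Frame Time:', got {time_kw!r}", ln)
    if not time_kw.endswith(":"):
        toks.next(":")
    frame_time = toks.next_float()

    n_channels = hierarchy.n_channels
    values = np.empty((n_frames, n_channels))
    for t in range(n_frames):
        for c in range(n_channels):
            if toks.done():
                raise BVHParseError(
                    f"motion data ended early: header declares Frames: {n_frames} "
                    f"({n_channels} channels) but data stops in frame {t + 1}"
                )
            values[t, c] = toks.next_float()
    if not toks.done():
        tok, ln = toks.peek()
        raise BVHParseError(
            f"trailing motion data beyond the declared Frames: {n_frames}", ln
        )
    return hierarchy, MotionSequence(frame_time=frame_time, channel_values=values)


def read_bvh(path) -> tuple[SkeletonHierarchy, MotionSequence]:
    """Read a BVH file; raises :class:`BVHParseError` with line numbers."""
    with open(path, "r") as fh:
        return parse_bvh(fh.read())


# ---------------------------------------------------------------------------
# writing


def _format_joint(j: Joint, depth: int, lines: list[str]) -> None:
    ind = "\t" * depth
    if j.is_end_site:
        lines.append(f"{ind}End Site")
        lines.append(f"{ind}{{")
        lines.append(f"{ind}\tOFFSET {j.offset[0]:.6f} {j.offset[1]:.6f} {j.offset[2]:.6f}")
        lines.append(f"{ind}}}")
        return
    kw = "ROOT" if depth == 0 else "JOINT"
    lines.append(f"{ind}{kw} {j.name}")
    lines.append(f"{ind}{{")
    lines.append(f"{ind}\tOFFSET {j.offset[0]:.6f} {j.offset[1]:.6f} {j.offset[2]:.6f}")
    if j.channels:
        lines.append(f"{ind}\tCHANNELS {len(j.channels)} " + " ".join(j.channels))
    for c in j.children:
        _format_joint(c, depth + 1, lines)
    lines.append(f"{ind}}}")


def format_bvh(hierarchy: SkeletonHierarchy, motion: MotionSequence) -> str:
    if motion.channel_values.shape[1] != hierarchy.n_channels:
        raise DimensionMismatchError(
            "motion channel count vs hierarchy", motion.channel_values.shape[1], hierarchy.n_channels
        )
    lines = ["HIERARCHY"]
    _format_joint(hierarchy.root, 0, lines)
    lines.append("MOTION")
    lines.append(f"Frames: {motion.n_frames}")
    lines.append(f"Frame Time: {motion.frame_time:.10g}")
    for row in motion.channel_values:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    return "\n".join(lines) + "\n"


def write_bvh(hierarchy: SkeletonHierarchy, motion: MotionSequence, path) -> None:
    """Serialize as standard BVH text (>= 6 significant digits per value)."""
    with open(path, "w") as fh:
        fh.write(format_bvh(hierarchy, motion))


# ---------------------------------------------------------------------------
# forward kinematics


def _channel_slices(hierarchy: SkeletonHierarchy) -> dict[str, slice]:
    out = {}
    start = 0
    for j in hierarchy.joints(include_end_sites=True):
        out[j.name] = slice(start, start + len(j.channels))
        start += len(j.channels)
    return out


def forward_kinematics(hierarchy: SkeletonHierarchy, motion: MotionSequence) -> PoseSequence:
    """World positions of every articulated joint at every frame.

    Each joint's local transform is its offset translation, plus its
    position channels (added to the translation), then its rotation channels
    composed intrinsically in the declared order (degrees). End Sites are
    excluded from the output: they carry no motion channels and the feature
    vector counts articulated joints only.
    """
    if motion.channel_values.shape[1] != hierarchy.n_channels:
        raise DimensionMismatchError(
            "motion channel count vs hierarchy", motion.channel_values.shape[1], hierarchy.n_channels
        )
    T = motion.n_frames
    slices = _channel_slices(hierarchy)
    names = hierarchy.joint_names()
    positions = np.empty((T, len(names), 3))
    index = {n: i for i, n in enumerate(names)}

    def visit(j: Joint, parent_R: np.ndarray, parent_p: np.ndarray):
        # parent_R: (T, 3, 3); parent_p: (T, 3)
        vals = motion.channel_values[:, slices[j.name]]
        local_t = np.tile(j.offset, (T, 1))
        rot_seq = ""
        rot_cols = []
        for k, ch in enumerate(j.channels):
            if ch in POSITION_CHANNELS:
                local_t[:, POSITION_CHANNELS.index(ch)] += vals[:, k]
            else:
                rot_seq += ch[0]  # 'X', 'Y' or 'Z'
                rot_cols.append(k)
        world_p = parent_p + np.einsum("tij,tj->ti", parent_R, local_t)
        if rot_seq:
            local_R = Rotation.from_euler(rot_seq, vals[:, rot_cols], degrees=True).as_matrix()
            world_R = np.einsum("tij,tjk->tik", parent_R, local_R)
        else:
            world_R = parent_R
        if not j.is_end_site:
            positions[:, index[j.name], :] = world_p
        for c in j.children:
            visit(c, world_R, world_p)

    eye = np.tile(np.eye(3), (T, 1, 1))
    visit(hierarchy.root, eye, np.zeros((T, 3)))
    return PoseSequence(positions=positions, joint_names=names, frame_time=motion.frame_time)


# ---------------------------------------------------------------------------
# normalization and flattening


def hip_normalize(poses: PoseSequence, root_joint: str | None = None) -> PoseSequence:
    """Subtract the root (hip) joint's position from every joint, per frame.

    The root sits at the origin in every output frame; inter-joint geometry
    is untouched. ``root_joint`` defaults to the first joint (the hierarchy
    root in FK output order).
    """
    if root_joint is None:
        root_idx = 0
    else:
        try:
            root_idx = poses.joint_names.index(root_joint)
        except ValueError:
            raise KeyError(
                f"joint {root_joint!r} not found; known joints: {poses.joint_names}"
            ) from None
    centered = poses.positions - poses.positions[:, root_idx : root_idx + 1, :]
    return PoseSequence(
        positions=centered, joint_names=list(poses.joint_names), frame_time=poses.frame_time
    )


def flatten_poses(poses: PoseSequence) -> np.ndarray:
    """Row t = (x1, y1, z1, ..., xJ, yJ, zJ) of frame t; shape (T, 3J)."""
    T, J, _ = poses.positions.shape
    return poses.positions.reshape(T, 3 * J)


def unflatten_poses(frames: np.ndarray, joint_names: list[str], frame_time: float) -> PoseSequence:
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    J = len(joint_names)
    if frames.shape[1] != 3 * J:
        raise DimensionMismatchError("flattened width vs 3*J", frames.shape[1], 3 * J)
    return PoseSequence(
        positions=frames.reshape(frames.shape[0], J, 3),
        joint_names=list(joint_names),
        frame_time=frame_time,
    )


def poses_to_csv(poses: PoseSequence, path) -> None:
    """Long-format export: columns frame, joint, x, y, z."""
    import pandas as pd

    T, J, _ = poses.positions.shape
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(T), J),
            "joint": np.tile(np.asarray(poses.joint_names, dtype=object), T),
            "x": poses.positions[:, :, 0].ravel(),
            "y": poses.positions[:, :, 1].ravel(),
            "z": poses.positions[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False)
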