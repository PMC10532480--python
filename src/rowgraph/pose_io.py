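"""OpenPose body25 keypoint I/O and skeleton-graph construction.

One rower, one video: each frame carries exactly 25 keypoints
(x, y, confidence) in body25 order.  Coordinates are raw pixels with
origin at the top-left; an undetected keypoint is (0, 0, 0).  Frames are
converted to 25-node skeleton graphs whose node features are the joint
coordinates (X only, Y only, or (X, Y)) and whose 24 edges form the fixed
body25 tree with constant edge feature 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "N_JOINTS",
    "JOINT_NAMES",
    "Keypoint",
    "PoseFrame",
    "PoseSequence",
    "SkeletonGraph",
    "PoseFormatError",
    "ModelMismatchError",
    "body25_edges",
    "frame_to_graph",
    "read_openpose_json",
    "write_openpose_json",
    "sequence_to_csv",
    "sequence_from_csv",
    "normalize_sequence",
    "interpolate_missing",
]

N_JOINTS = 25

#: body25 joint names, index order as emitted by OpenPose.
JOINT_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

MODES = ("1D-X", "1D-Y", "2D")


class PoseFormatError(ValueError):
    """Raised when a keypoint record does not follow the OpenPose layout."""


class ModelMismatchError(ValueError):
    """Raised when the keypoint count is not 25 (e.g. COCO-18 input)."""


class Keypoint(NamedTuple):
    x: float
    y: float
    c: float


@dataclass
class PoseFrame:
    """One video frame: 25 body25 keypoints as a (25, 3) array."""

    index: int
    keypoints: np.ndarray  # (25, 3) columns x, y, c
    missing: bool = False

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        if self.keypoints.shape != (N_JOINTS, 3):
            raise ModelMismatchError(
                f"frame {self.index}: expected {N_JOINTS} keypoints, got "
                f"shape {self.keypoints.shape} (wrong OpenPose model?)"
            )
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def joints(self) -> List[Keypoint]:
        return [Keypoint(*row) for row in self.keypoints]

    @property
    def xy(self) -> np.ndarray:
        return self.keypoints[:, :2]


@dataclass
class PoseSequence:
    """Ordered pose frames of one rower's video at a fixed frame rate."""

    frames: List[PoseFrame]
    fps: float = 60.0
    source_id: str = ""
    width: int = 1920
    height: int = 1080

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("a pose sequence needs at least one frame")
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """(L, 25, 2) array of raw pixel coordinates."""
        return np.stack([f.keypoints[:, :2] for f in self.frames])

    @property
    def confidence(self) -> np.ndarray:
        return np.stack([f.keypoints[:, 2] for f in self.frames])


@dataclass
class SkeletonGraph:
    """25-node skeleton with coordinate node features and the body25 tree."""

    node_features: np.ndarray  # (25, 1) or (25, 2)
    edges: np.ndarray          # (24, 2) int
    edge_features: np.ndarray  # (24, 1), constant 1
    mode: str

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.intp)
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64)
        want = 2 if self.mode == "2D" else 1
        if self.node_features.shape != (N_JOINTS, want):
            raise ValueError(
                f"mode {self.mode} expects node features ({N_JOINTS}, {want})"
            )


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------

_BODY25_EDGES = (
    (1, 0),                       # neck - nose
    (1, 2), (2, 3), (3, 4),       # right arm
    (1, 5), (5, 6), (6, 7),       # left arm
    (1, 8),                       # trunk: neck - mid hip
    (8, 9), (9, 10), (10, 11),    # right leg
    (8, 12), (12, 13), (13, 14),  # left leg
    (0, 15), (15, 17),            # right eye / ear
    (0, 16), (16, 18),            # left eye / ear
    (14, 19), (19, 20), (14, 21),  # left foot
    (11, 22), (22, 23), (11, 24),  # right foot
)


def body25_edges() -> List[tuple]:
    """The 24 undirected edges of the body25 skeleton (a tree over 25 nodes)."""
    return [tuple(e) for e in _BODY25_EDGES]


def frame_to_graph(frame: PoseFrame, mode: str) -> SkeletonGraph:
    """Convert a pose frame to a skeleton graph in the given input mode.

    Node i carries (x_i) in 1D-X mode, (y_i) in 1D-Y mode and (x_i, y_i)
    in 2D mode; detection confidence is not a node feature.  All graphs
    share the body25 topology with constant edge feature 1.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    xy = frame.keypoints[:, :2]
    if mode == "1D-X":
        feats = xy[:, :1]
    elif mode == "1D-Y":
        feats = xy[:, 1:2]
    else:
        feats = xy
    edges = np.array(_BODY25_EDGES, dtype=np.intp)
    return SkeletonGraph(
        node_features=feats.copy(),
        edges=edges,
        edge_features=np.ones((edges.shape[0], 1)),
        mode=mode,
    )


# ----------------------------------------------------------------------
# OpenPose JSON reading / writing
# ----------------------------------------------------------------------

def _parse_frame_record(record: dict, index: int) -> PoseFrame:
    if not isinstance(record, dict) or "people" not in record:
        raise PoseFormatError(
            f"frame {index}: record is not an OpenPose people dict"
        )
    people = record["people"]
    if not people:
        return PoseFrame(index, np.zeros((N_JOINTS, 3)), missing=True)
    best, best_conf = None, -1.0
    for person in people:
        flat = person.get("pose_keypoints_2d")
        if flat is None:
            raise PoseFormatError(
                f"frame {index}: person without pose_keypoints_2d"
            )
        flat = np.asarray(flat, dtype=np.float64)
        if flat.size % 3 != 0:
            raise PoseFormatError(
                f"frame {index}: keypoint list length {flat.size} is not a "
                "multiple of 3"
            )
        if flat.size != N_JOINTS * 3:
            raise ModelMismatchError(
                f"frame {index}: {flat.size // 3} keypoints per person; "
                f"expected {N_JOINTS} (body25 model required)"
            )
        kps = flat.reshape(N_JOINTS, 3)
        conf = float(kps[:, 2].mean())
        if conf > best_conf:
            best, best_conf = kps, conf
    return PoseFrame(index, best)


def read_openpose_json(
    path,
    fps: float = 60.0,
    source_id: str = "",
    width: int = 1920,
    height: int = 1080,
) -> PoseSequence:
    """Read OpenPose body25 output into a :class:`PoseSequence`.

    ``path`` may be a directory of per-frame ``*_keypoints.json`` files
    (sorted lexically, OpenPose's zero-padded naming), a JSON file holding
    a list of frame records, or a single-frame JSON file.  When several
    people are detected in a frame, the one with the highest mean
    confidence is kept; frames with an empty people list become all-zero
    frames flagged as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise PoseFormatError(f"no JSON keypoint files in {path}")
        records = []
        for f in files:
            with open(f) as fh:
                records.append(json.load(fh))
    else:
        with open(path) as fh:
            payload = json.load(fh)
        records = payload if isinstance(payload, list) else [payload]
    frames = [_parse_frame_record(rec, i) for i, rec in enumerate(records)]
    if not source_id:
        source_id = path.stem if path.is_file() else path.name
    return PoseSequence(frames, fps=fps, source_id=source_id,
                        width=width, height=height)


def write_openpose_json(seq: PoseSequence, out_dir, prefix: str = "frame"):
    """Write one OpenPose-layout JSON file per frame (round-trips exactly)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for frame in seq.frames:
        people = [] if frame.missing else [
            {"pose_keypoints_2d": frame.keypoints.ravel().tolist()}
        ]
        record = {"version": 1.3, "people": people}
        name = f"{prefix}_{frame.index:012d}_keypoints.json"
        with open(out_dir / name, "w") as fh:
            json.dump(record, fh)


# ----------------------------------------------------------------------
# CSV export / import
# ----------------------------------------------------------------------

def sequence_to_csv(seq: PoseSequence, path) -> None:
    """Long-format export: one row per (frame, joint)."""
    rows = []
    for frame in seq.frames:
        for j in range(N_JOINTS):
            x, y, c = frame.keypoints[j]
            rows.append((frame.index, j, x, y, c))
    df = pd.DataFrame(rows, columns=["frame", "joint_id", "x", "y", "c"])
    df.to_csv(path, index=False)


def sequence_from_csv(path, fps: float = 60.0, source_id: str = "",
                      width: int = 1920, height: int = 1080) -> PoseSequence:
    df = pd.read_csv(path)
    frames = []
    for idx, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("joint_id")
        kps = grp[["x", "y", "c"]].to_numpy()
        missing = bool(np.all(kps == 0))
        frames.append(PoseFrame(int(idx), kps, missing=missing))
    return PoseSequence(frames, fps=fps, source_id=source_id,
                        width=width, height=height)


# ----------------------------------------------------------------------
# optional preprocessing (off by default in the pipeline)
# ----------------------------------------------------------------------

def normalize_sequence(seq: PoseSequence) -> PoseSequence:
    """Mid-hip-centred, trunk-length-scaled copy of a sequence.

    Optional preprocessing; the pipeline default keeps raw pixels so that
    dissimilarity magnitudes reflect absolute image-space differences.
    """
    out = []
    for frame in seq.frames:
        kps = frame.keypoints.copy()
        if frame.missing:
            out.append(PoseFrame(frame.index, kps, missing=True))
            continue
        midhip, neck = kps[8, :2], kps[1, :2]
        trunk = float(np.linalg.norm(neck - midhip))
        scale = trunk if trunk > 0 else 1.0
        detected = kps[:, 2] > 0
        kps[detected, :2] = (kps[detected, :2] - midhip) / scale
        out.append(PoseFrame(frame.index, kps, missing=False))
    return PoseSequence(out, fps=seq.fps, source_id=seq.source_id,
                        width=seq.width, height=seq.height)


def interpolate_missing(seq: PoseSequence) -> PoseSequence:
    """Linearly interpolate undetected keypoints (c = 0) in time.

    Optional: the default pipeline keeps (0, 0, 0) dropouts as emitted by
    OpenPose.  Keypoints missing at the sequence boundary are filled by
    nearest-neighbour extension.
    """
    coords = seq.coords.copy()          # (L, 25, 2)
    conf = seq.confidence.copy()        # (L, 25)
    L = len(seq)
    t = np.arange(L, dtype=float)
    for j in range(N_JOINTS):
        ok = conf[:, j] > 0
        if ok.all() or not ok.any():
            continue
        for d in range(2):
            coords[~ok, j, d] = np.interp(t[~ok], t[ok], coords[ok, j, d])
        conf[~ok, j] = np.interp(t[~ok], t[ok], conf[ok, j])
    frames = []
    for i, frame in enumerate(seq.frames):
        kps = np.column_stack([coords[i], conf[:, :][i]])
        frames.append(PoseFrame(frame.index, kps, missing=False))
    return PoseSequence(frames, fps=seq.fps, source_id=seq.source_id,
                        width=seq.width, height=seq.height)
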