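"""Dissimilarity scoring, start alignment, time-period smoothing, rosters.

Given per-frame graph vectors of two rowers, the per-frame distance is
the Euclidean norm of the embedding difference and the aggregate
dissimilarity score is the root-mean over frames of the squared
distances (RMS).  A lower score means better-matched rowing postures.

Because two videos rarely start at the same stroke phase, an integer
start-frame offset in [-100, 100] is searched that minimises the mean
embedding distance over a comparison window, and both sequences are
truncated to their aligned overlap before scoring.  For trend analysis
the framewise series is smoothed into consecutive 100-frame segment
means ("time-period similarity", TPS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .graph_model import (
    GraphVector,
    ModelConfig,
    ModelParams,
    embed_frames,
    embed_sequence,
)
from .pose_io import PoseSequence

__all__ = [
    "DissimilarityRecord",
    "AlignmentResult",
    "TPSSeries",
    "DissimilarityMatrix",
    "frame_distances",
    "dissim_score",
    "align_start",
    "tps",
    "compare_pair",
    "dissim_matrix",
    "rank_pairs",
    "plot_series",
    "plot_skeleton_overlay",
]


def _as_gf_array(gfs) -> np.ndarray:
    """Accept a list of GraphVector or an (L, g) array."""
    if isinstance(gfs, np.ndarray):
        return gfs if gfs.ndim == 2 else gfs[:, None]
    return np.stack([np.atleast_1d(g.gf) for g in gfs])


@dataclass
class DissimilarityRecord:
    """Framewise distances and aggregate score for one rower pair."""

    p1: str
    p2: str
    distances: np.ndarray            # (L,) per-frame Euclidean distances
    score: float                     # RMS aggregate
    score_squared: float             # mean of squared distances
    offset: Optional[int] = None     # alignment offset used, if any


@dataclass
class AlignmentResult:
    """Outcome of the start-frame offset search."""

    s1: int
    s2: int
    offset: int
    score: float
    at_boundary: bool = False

    def __post_init__(self):
        assert self.s2 == self.s1 + self.offset


@dataclass
class TPSSeries:
    """Segment means of a framewise dissimilarity series."""

    means: np.ndarray
    ranges: List[Tuple[int, int]]    # [start, end) frame ranges
    segment_length: int
    partial_last: bool


@dataclass
class DissimilarityMatrix:
    """Symmetric all-pairs score matrix over a roster."""

    ids: List[str]
    values: np.ndarray               # (n, n), zero diagonal
    best_per_column: np.ndarray      # row index of the column minimum
    worst_per_column: np.ndarray     # row index of the column maximum


# ----------------------------------------------------------------------
# core scoring
# ----------------------------------------------------------------------

def frame_distances(gf1, gf2) -> np.ndarray:
    """Per-frame Euclidean distances between two graph-vector series."""
    a, b = _as_gf_array(gf1), _as_gf_array(gf2)
    L = min(len(a), len(b))
    if L == 0:
        raise ValueError("zero-length overlap between embedding series")
    return np.linalg.norm(a[:L] - b[:L], axis=1)


def dissim_score(distances: Sequence[float],
                 squared: bool = False) -> float:
    """Aggregate dissimilarity: RMS of the per-frame distances.

    With ``squared=True`` the square root is omitted (mean squared
    distance), the reading suggested by "squared Euclidean distance" in
    matrix captions; both conventions rank pairs identically.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size < 1:
        raise ValueError("need at least one frame distance")
    ms = float(np.mean(d**2))
    return ms if squared else float(np.sqrt(ms))


# ----------------------------------------------------------------------
# start-frame alignment
# ----------------------------------------------------------------------

def align_start(gf1, gf2, s1: Optional[int] = None, window: int = 100,
                max_offset: int = 100) -> AlignmentResult:
    """Find the integer start offset putting two videos on one baseline.

    Minimises, over offsets f in [-max_offset, max_offset], the mean
    embedding distance between gf1[s1 : s1+window] and
    gf2[s1+f : s1+f+window].  Ties break toward the smallest |f| and
    then the negative offset.  ``at_boundary`` flags a minimiser at the
    edge of the search range (the true shift may lie outside it).
    """
    a, b = _as_gf_array(gf1), _as_gf_array(gf2)
    if window < 1:
        raise ValueError("window must be >= 1")
    if s1 is None:
        s1 = max_offset
    if s1 - max_offset < 0 or s1 + window > len(a):
        raise ValueError(
            f"sequence 1 too short: need frames [{s1 - max_offset}, "
            f"{s1 + window}) within [0, {len(a)})"
        )
    if s1 - max_offset < 0 or s1 + max_offset + window > len(b):
        raise ValueError(
            f"sequence 2 too short: need frames [{s1 - max_offset}, "
            f"{s1 + max_offset + window}) within [0, {len(b)})"
        )
    ref = a[s1:s1 + window]
    offsets = np.arange(-max_offset, max_offset + 1)
    costs = np.empty(offsets.shape[0])
    for k, f in enumerate(offsets):
        seg = b[s1 + f:s1 + f + window]
        costs[k] = float(np.mean(np.linalg.norm(ref - seg, axis=1)))
    order = sorted(range(len(offsets)),
                   key=lambda k: (costs[k], abs(offsets[k]), offsets[k]))
    kbest = order[0]
    f_star = int(offsets[kbest])
    return AlignmentResult(
        s1=s1, s2=s1 + f_star, offset=f_star, score=float(costs[kbest]),
        at_boundary=abs(f_star) == max_offset,
    )


# ----------------------------------------------------------------------
# time-period similarity
# ----------------------------------------------------------------------

def tps(distances: Sequence[float], segment_length: int = 100) -> TPSSeries:
    """Consecutive non-overlapping segment means of a framewise series.

    A trailing partial segment is averaged over its actual length and
    flagged.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size < 1:
        raise ValueError("distances must be non-empty")
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    n_seg = int(np.ceil(d.size / segment_length))
    means, ranges = [], []
    for k in range(n_seg):
        lo = k * segment_length
        hi = min(lo + segment_length, d.size)
        means.append(float(d[lo:hi].mean()))
        ranges.append((lo, hi))
    partial = (d.size % segment_length) != 0
    return TPSSeries(np.asarray(means), ranges, segment_length, partial)


# ----------------------------------------------------------------------
# pairwise comparison and roster matrices
# ----------------------------------------------------------------------

def _intra_embeddings(seq: PoseSequence, params: ModelParams,
                      config: ModelConfig) -> np.ndarray:
    """Partner-independent embeddings: the GEM forward pass.  For a GMN
    this is its intra-graph part (zero cross message), used only for the
    offset search, whose cost is linear in the 201 candidate offsets."""
    if config.model_type == "GEM":
        return np.asarray(embed_frames(seq.coords, params, config))
    from .matching import embed_frame_pairs  # local import, cycle-free
    g1, _ = embed_frame_pairs(seq.coords, seq.coords, params, config)
    return np.asarray(g1)


def compare_pair(seq1: PoseSequence, seq2: PoseSequence,
                 params: ModelParams, config: ModelConfig,
                 align: bool = True, window: int = 100,
                 max_offset: int = 100,
                 squared: bool = False) -> DissimilarityRecord:
    """Embed, optionally align, truncate to the overlap and score a pair.

    GEM embeds each rower independently; a GMN re-embeds the aligned
    frames jointly, so its embeddings are pair-specific.
    """
    if config.model_type == "GEM":
        gf1 = np.asarray(embed_frames(seq1.coords, params, config))
        gf2 = np.asarray(embed_frames(seq2.coords, params, config))
        s1 = s2 = 0
        offset = None
        if align:
            res = align_start(gf1, gf2, window=window, max_offset=max_offset)
            s1, s2, offset = res.s1, res.s2, res.offset
        L = min(len(gf1) - s1, len(gf2) - s2)
        d = frame_distances(gf1[s1:s1 + L], gf2[s2:s2 + L])
    else:
        from .matching import embed_frame_pairs
        s1 = s2 = 0
        offset = None
        if align:
            e1 = _intra_embeddings(seq1, params, config)
            e2 = _intra_embeddings(seq2, params, config)
            res = align_start(e1, e2, window=window, max_offset=max_offset)
            s1, s2, offset = res.s1, res.s2, res.offset
        c1, c2 = seq1.coords[s1:], seq2.coords[s2:]
        L = min(len(c1), len(c2))
        g1, g2 = embed_frame_pairs(c1[:L], c2[:L], params, config)
        d = frame_distances(np.asarray(g1), np.asarray(g2))
    return DissimilarityRecord(
        p1=seq1.source_id, p2=seq2.source_id, distances=d,
        score=dissim_score(d), score_squared=dissim_score(d, squared=True),
        offset=offset,
    )


def dissim_matrix(roster: Sequence[PoseSequence], params: ModelParams,
                  config: ModelConfig, align: bool = True,
                  window: int = 100, max_offset: int = 100,
                  squared: bool = False) -> DissimilarityMatrix:
    """Symmetric all-pairs dissimilarity matrix over a roster.

    Each column's minimum marks the most similar partner for that rower
    and the maximum the least similar one (the pairing-table reading).
    """
    n = len(roster)
    if n < 2:
        raise ValueError("a roster needs at least 2 rowers")
    ids = [seq.source_id or f"rower-{i}" for i, seq in enumerate(roster)]
    values = np.zeros((n, n))
    # GEM embeddings are partner-independent: compute once per rower
    cache = None
    if config.model_type == "GEM":
        cache = [np.asarray(embed_frames(s.coords, params, config))
                 for s in roster]
    for i in range(n):
        for j in range(i + 1, n):
            if cache is not None:
                gf1, gf2 = cache[i], cache[j]
                s1 = s2 = 0
                if align:
                    res = align_start(gf1, gf2, window=window,
                                      max_offset=max_offset)
                    s1, s2 = res.s1, res.s2
                L = min(len(gf1) - s1, len(gf2) - s2)
                d = frame_distances(gf1[s1:s1 + L], gf2[s2:s2 + L])
                score = dissim_score(d, squared=squared)
            else:
                rec = compare_pair(roster[i], roster[j], params, config,
                                   align=align, window=window,
                                   max_offset=max_offset)
                score = rec.score_squared if squared else rec.score
            values[i, j] = values[j, i] = score
    off = values + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    best = off.argmin(axis=0)
    worst = values.argmax(axis=0)
    return DissimilarityMatrix(ids, values, best, worst)


def rank_pairs(matrix: DissimilarityMatrix) -> List[Tuple[Tuple[str, str], float]]:
    """Unordered pairs sorted ascending by score (most similar first);
    ties break lexicographically by (row index, column index)."""
    n = len(matrix.ids)
    entries = [
        ((i, j), matrix.values[i, j])
        for i in range(n) for j in range(i + 1, n)
    ]
    entries.sort(key=lambda e: (e[1], e[0][0], e[0][1]))
    return [((matrix.ids[i], matrix.ids[j]), float(v))
            for (i, j), v in entries]


# ----------------------------------------------------------------------
# minimal plotting
# ----------------------------------------------------------------------

def plot_series(records, path, tps_segment: Optional[int] = None,
                labels: Optional[Sequence[str]] = None) -> None:
    """Framewise (or TPS-smoothed) dissimilarity curves for rower pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    styles = ["g-", "r--", "b-.", "k:"]
    for k, rec in enumerate(records):
        label = labels[k] if labels else f"{rec.p1} vs {rec.p2}"
        if tps_segment:
            series = tps(rec.distances, tps_segment)
            x = [0.5 * (lo + hi) for lo, hi in series.ranges]
            ax.plot(x, series.means, styles[k % len(styles)], label=label)
        else:
            ax.plot(rec.distances, styles[k % len(styles)], label=label)
    ax.set_xlabel("frame")
    ax.set_ylabel("dissimilarity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_skeleton_overlay(frame1, frame2, path) -> None:
    """Superimpose two skeletons (visual pose-match check)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .pose_io import body25_edges

    fig, ax = plt.subplots(figsize=(6, 5))
    for frame, color in ((frame1, "red"), (frame2, "black")):
        xy = frame.keypoints[:, :2]
        for a, b in body25_edges():
            if frame.keypoints[a, 2] > 0 and frame.keypoints[b, 2] > 0:
                ax.plot([xy[a, 0], xy[b, 0]], [xy[a, 1], xy[b, 1]],
                        color=color, lw=1.5)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
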