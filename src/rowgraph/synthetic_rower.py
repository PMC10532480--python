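"""Kinematic rowing-stroke simulator emitting body25 keypoint sequences.

A sagittal-plane (side camera) articulated model of an ergometer rower:
the hip slides horizontally with the stroke cycle, the knee and elbow are
placed by two-link inverse kinematics with constant segment lengths, and
the trunk pivots between forward lean at the catch and layback at the
finish.  The stroke cycle catch -> drive -> finish -> recovery is a
piecewise sinusoid in the cycle fraction, with an asymmetric drive
fraction (the drive is faster than the recovery).

Controllable structure: per-rower stroke period / phase / amplitudes
(style), i.i.d. Gaussian keypoint noise, dropout of whole keypoints to
(0, 0, 0), and a slow "fatigue" drift that lengthens the stroke period
over time so that an initially synchronised pair gradually desynchronises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .pose_io import N_JOINTS, PoseFrame, PoseSequence

__all__ = [
    "StrokeProfile",
    "RowerSpec",
    "Roster",
    "simulate",
    "make_roster",
]

# constant segment lengths (pixels) of the articulated figure
_SHANK = 180.0
_THIGH = 200.0
_TRUNK = 260.0
_UPPER_ARM = 140.0
_FOREARM = 150.0

_ANKLE = np.array([700.0, 820.0])   # fixed foot stretcher
_HIP_Y = 760.0                      # seat height
_HIP_X_CATCH = 120.0                # hip offset from ankle at the catch


@dataclass(frozen=True)
class StrokeProfile:
    """Stroke-style parameters of one rower.

    period
        frames per stroke cycle (>= 4); at 60 fps a period of 120 frames
        is 30 strokes/min, a typical steady-state ergometer rate.
    phase
        initial fraction of the cycle in [0, 1); a phase difference of
        k/period between two rowers is exactly a k-frame time shift.
    seat_travel
        horizontal hip excursion over the drive, pixels.
    lean_catch, lean_finish
        trunk angle from vertical at catch (forward, negative) and finish
        (layback, positive), radians.
    wrist_lift
        vertical rise of the handle from catch to finish, pixels.
    drive_fraction
        fraction of the cycle spent on the drive (catch -> finish).
    """

    period: float = 120.0
    phase: float = 0.0
    seat_travel: float = 240.0
    lean_catch: float = -0.35
    lean_finish: float = 0.30
    wrist_lift: float = 60.0
    drive_fraction: float = 0.45
    style_id: str = "default"

    def __post_init__(self):
        if self.period < 4:
            raise ValueError("stroke period must be >= 4 frames")
        if not (0.0 <= self.phase < 1.0):
            raise ValueError("phase must be in [0, 1)")
        if self.seat_travel < 0 or self.wrist_lift < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (0.05 < self.drive_fraction < 0.95):
            raise ValueError("drive_fraction must lie in (0.05, 0.95)")


@dataclass(frozen=True)
class RowerSpec:
    """A stroke profile plus observation noise, dropout, drift and seed."""

    profile: StrokeProfile = field(default_factory=StrokeProfile)
    noise_sigma: float = 0.0          # px, i.i.d. Gaussian per coordinate
    dropout_rate: float = 0.0         # probability a keypoint is (0,0,0)
    drift_rate: float = 0.0           # fractional period change per 1000 frames
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


def _cycle_progress(u: np.ndarray, drive_fraction: float) -> np.ndarray:
    """Stroke progress s in [0, 1] from cycle fraction u in [0, 1).

    s = 0 at the catch, s = 1 at the finish; the drive occupies
    ``drive_fraction`` of the cycle, the recovery the rest.
    """
    r = drive_fraction
    s = np.where(
        u < r,
        0.5 - 0.5 * np.cos(np.pi * u / r),
        0.5 + 0.5 * np.cos(np.pi * (u - r) / (1.0 - r)),
    )
    return s


def _two_link_ik(p0: np.ndarray, p1: np.ndarray, l0: float, l1: float,
                 side: float) -> np.ndarray:
    """Middle joint of a two-link chain from p0 to p1 (vectorised, (L,2)).

    ``side`` selects which side of the p0-p1 line the joint bends to
    (+1 along the left-hand normal of the p0->p1 direction).
    """
    d = p1 - p0
    dist = np.linalg.norm(d, axis=-1, keepdims=True)
    # clamp so the chain never has to overextend
    max_reach = (l0 + l1) * 0.999
    scale = np.minimum(1.0, max_reach / np.maximum(dist, 1e-9))
    p1c = p0 + d * scale
    d = p1c - p0
    dist = np.linalg.norm(d, axis=-1, keepdims=True)
    u = d / np.maximum(dist, 1e-9)
    a = (l0**2 - l1**2 + dist**2) / (2.0 * np.maximum(dist, 1e-9))
    h = np.sqrt(np.maximum(l0**2 - a**2, 0.0))
    perp = np.stack([-u[..., 1], u[..., 0]], axis=-1)
    return p0 + a * u + side * h * perp


def _skeleton_xy(s: np.ndarray, profile: StrokeProfile) -> np.ndarray:
    """Noise-free joint coordinates (L, 25, 2) from stroke progress s (L,)."""
    L = s.shape[0]
    s = s[:, None]
    ankle = np.broadcast_to(_ANKLE, (L, 2))

    hip = np.column_stack([
        _ANKLE[0] + _HIP_X_CATCH + profile.seat_travel * s[:, 0],
        np.full(L, _HIP_Y),
    ])
    # anchor the leg chain at the right hip (the skeleton edge endpoint)
    # so the thigh edge length stays exactly constant
    rhip = hip + np.array([0.0, 8.0])
    knee = _two_link_ik(ankle, rhip, _SHANK, _THIGH, side=-1.0)

    theta = profile.lean_catch + (profile.lean_finish - profile.lean_catch) * s
    neck = hip + _TRUNK * np.column_stack(
        [np.sin(theta[:, 0]), -np.cos(theta[:, 0])]
    )
    shoulder = neck + np.array([0.0, 20.0])

    wrist = np.column_stack([
        (1.0 - s[:, 0]) * (_ANKLE[0] + 40.0) + s[:, 0] * (hip[:, 0] + 20.0),
        740.0 - profile.wrist_lift * s[:, 0],
    ])
    elbow = _two_link_ik(shoulder, wrist, _UPPER_ARM, _FOREARM, side=-1.0)

    # head cluster: rower faces the flywheel (negative x)
    nose = neck + np.array([-28.0, -36.0])
    xy = np.zeros((L, N_JOINTS, 2))
    xy[:, 0] = nose
    xy[:, 1] = neck
    xy[:, 2] = shoulder                      # RShoulder
    xy[:, 3] = elbow                         # RElbow
    xy[:, 4] = wrist                         # RWrist
    # out-of-plane (left) arm mirrored with a small constant offset
    off = np.array([8.0, 4.0])
    xy[:, 5] = shoulder + off
    xy[:, 6] = elbow + off
    xy[:, 7] = wrist + off
    xy[:, 8] = hip                           # MidHip
    xy[:, 9] = rhip                          # RHip
    xy[:, 10] = knee
    xy[:, 11] = ankle                        # RAnkle
    xy[:, 12] = rhip + off                   # LHip
    xy[:, 13] = knee + off
    xy[:, 14] = ankle + off
    xy[:, 15] = neck + np.array([-34.0, -52.0])    # REye
    xy[:, 16] = neck + np.array([-26.0, -56.0])    # LEye
    xy[:, 17] = neck + np.array([-6.0, -50.0])     # REar
    xy[:, 18] = neck + np.array([2.0, -54.0])      # LEar
    xy[:, 19] = ankle + off + np.array([42.0, 18.0])   # LBigToe
    xy[:, 20] = ankle + off + np.array([50.0, 14.0])   # LSmallToe
    xy[:, 21] = ankle + off + np.array([-14.0, 12.0])  # LHeel
    xy[:, 22] = ankle + np.array([42.0, 18.0])     # RBigToe
    xy[:, 23] = ankle + np.array([50.0, 14.0])     # RSmallToe
    xy[:, 24] = ankle + np.array([-14.0, 12.0])    # RHeel
    return xy


def simulate(
    spec: RowerSpec,
    n_frames: int = 3600,
    fps: float = 60.0,
    frame_size: Tuple[int, int] = (1920, 1080),
    source_id: Optional[str] = None,
) -> PoseSequence:
    """Simulate a rower's keypoint sequence.

    Deterministic given ``spec.seed``.  With zero noise and zero drift the
    output is exactly periodic with the profile's period; positive drift
    slowly lengthens the period ("fatigue"), degrading stroke consistency.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    profile = spec.profile
    t = np.arange(n_frames, dtype=np.float64)
    period_t = profile.period * (1.0 + spec.drift_rate * t / 1000.0)
    if np.any(period_t < 4.0):
        raise ValueError("drift drives the stroke period below 4 frames")
    if spec.drift_rate == 0.0:
        # direct form keeps noise-free output exactly periodic: an
        # incremental cumsum would accumulate ~1e-12 phase error
        p0 = profile.phase * profile.period
        u = np.mod(t + p0, profile.period) / profile.period
    else:
        # phase advances by 1/period(t) each frame
        phi = profile.phase + np.concatenate(
            [[0.0], np.cumsum(1.0 / period_t[:-1])]
        )
        u = np.mod(phi, 1.0)
    s = _cycle_progress(u, profile.drive_fraction)
    xy = _skeleton_xy(s, profile)

    rng = np.random.default_rng(spec.seed)
    conf = np.clip(rng.normal(0.95, 0.02, size=(n_frames, N_JOINTS)), 0.0, 1.0)
    if spec.noise_sigma > 0:
        xy = xy + rng.normal(0.0, spec.noise_sigma, size=xy.shape)
    if spec.dropout_rate > 0:
        drop = rng.random((n_frames, N_JOINTS)) < spec.dropout_rate
        xy[drop] = 0.0
        conf[drop] = 0.0

    w, h = frame_size
    np.clip(xy[..., 0], 0.0, w - 1.0, out=xy[..., 0])
    np.clip(xy[..., 1], 0.0, h - 1.0, out=xy[..., 1])

    frames = [
        PoseFrame(i, np.column_stack([xy[i], conf[i]]))
        for i in range(n_frames)
    ]
    return PoseSequence(
        frames, fps=fps,
        source_id=source_id or f"sim-{profile.style_id}-{spec.seed}",
        width=w, height=h,
    )


@dataclass
class Roster:
    """Simulated rowers plus planted ground-truth similarity structure."""

    sequences: List[PoseSequence]
    style_ids: List[str]
    specs: List[RowerSpec]
    best_pair: Tuple[int, int]
    worst_pair: Tuple[int, int]

    @property
    def within_style_pairs(self) -> List[Tuple[int, int]]:
        return [
            (i, j)
            for i in range(len(self.style_ids))
            for j in range(i + 1, len(self.style_ids))
            if self.style_ids[i] == self.style_ids[j]
        ]

    @property
    def cross_style_pairs(self) -> List[Tuple[int, int]]:
        return [
            (i, j)
            for i in range(len(self.style_ids))
            for j in range(i + 1, len(self.style_ids))
            if self.style_ids[i] != self.style_ids[j]
        ]


def _style_distance(a: StrokeProfile, b: StrokeProfile) -> float:
    return (
        abs(a.period - b.period) / max(a.period, b.period)
        + abs(a.seat_travel - b.seat_travel) / 240.0
        + abs(a.lean_finish - b.lean_finish)
        + abs(a.lean_catch - b.lean_catch)
    )


def make_roster(
    n: int,
    styles: Sequence[StrokeProfile],
    assignment: Optional[Sequence[int]] = None,
    noise_sigma: float = 2.0,
    phase_step_frames: float = 10.0,
    drift_rates: Optional[Sequence[float]] = None,
    n_frames: int = 600,
    fps: float = 60.0,
    seed: int = 0,
) -> Roster:
    """Build a roster of ``n`` simulated rowers over the given styles.

    Rowers sharing a style differ only by noise seed and by a phase shift
    of ``phase_step_frames`` frames per same-style sibling (so alignment
    has a known integer shift to recover).  The planted best pair is the
    first same-style pair with equal phase rank; the planted worst pair is
    the cross-style pair with the largest style-parameter distance.
    """
    if n < 2:
        raise ValueError("a roster needs at least 2 rowers")
    if not styles:
        raise ValueError("at least one stroke style is required")
    if assignment is None:
        assignment = [i % len(styles) for i in range(n)]
    if len(assignment) != n:
        raise ValueError("assignment length must equal n")

    specs, sequences, style_ids = [], [], []
    sibling_count: dict = {}
    for i in range(n):
        style = styles[assignment[i]]
        k = sibling_count.get(assignment[i], 0)
        sibling_count[assignment[i]] = k + 1
        # sibling k starts k * phase_step_frames frames later (lags), so
        # aligning rower 0 against sibling k recovers +k*step exactly
        shift = -(phase_step_frames * k) / style.period
        profile = replace(style, phase=float(np.mod(style.phase + shift, 1.0)))
        drift = drift_rates[i] if drift_rates is not None else 0.0
        spec = RowerSpec(profile=profile, noise_sigma=noise_sigma,
                         drift_rate=drift, seed=seed * 1009 + i)
        specs.append(spec)
        sequences.append(simulate(spec, n_frames=n_frames, fps=fps,
                                  source_id=f"rower-{i}"))
        style_ids.append(style.style_id)

    # planted ground truth
    best_pair = None
    for i in range(n):
        for j in range(i + 1, n):
            if assignment[i] == assignment[j]:
                best_pair = (i, j)
                break
        if best_pair:
            break
    if best_pair is None:  # all styles distinct: closest styles win
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        best_pair = min(pairs, key=lambda p: _style_distance(
            specs[p[0]].profile, specs[p[1]].profile))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if assignment[i] != assignment[j]]
    if pairs:
        worst_pair = max(pairs, key=lambda p: _style_distance(
            specs[p[0]].profile, specs[p[1]].profile))
    else:
        worst_pair = (0, n - 1)
    return Roster(sequences, style_ids, specs, best_pair, worst_pair)
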