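"""Contrastive training of the GEM / GMN embedding parameters.

Positive (similar) pairs are a frame against the same frame with small
Gaussian coordinate jitter — the magnitude of keypoint-detector noise;
negative (dissimilar) pairs are frames from different rowers, or frames
of one rower at clearly different stroke phases (at least a quarter
period apart).  The margin contrastive loss

    similar:     d^2
    dissimilar:  max(0, margin - d)^2

is minimised with Adam over the embedding distance d = ||GF_a - GF_b||.
One global seed governs sampling, jitter and weight initialisation, so a
run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .graph_model import (
    ModelConfig,
    ModelParams,
    embed_frames,
    init_params,
    mode_features,
)
from .matching import embed_frame_pairs
from .pose_io import N_JOINTS, PoseSequence, SkeletonGraph, frame_to_graph

__all__ = [
    "TrainingConfig",
    "TrainingPair",
    "TrainingDiverged",
    "sample_pairs",
    "contrastive_loss",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the contrastive training loop.

    jitter_scale (pixels) sets the coordinate noise used to build
    positive pairs; period_hint (frames) enables same-rower negatives at
    least a quarter stroke apart when only one sequence is available.
    """

    iterations: int = 5000
    margin: float = 1.0
    learning_rate: float = 1e-3
    batch_pairs: int = 16
    jitter_scale: float = 3.0
    period_hint: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.batch_pairs < 2:
            raise ValueError("batch_pairs must be >= 2")


@dataclass
class TrainingPair:
    graph_a: SkeletonGraph
    graph_b: SkeletonGraph
    label: str                  # "similar" or "dissimilar"

    def __post_init__(self):
        if self.label not in ("similar", "dissimilar"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.graph_a.mode != self.graph_b.mode:
            raise ValueError("pair members must share the input mode")


def contrastive_loss(d: float, label: str, margin: float) -> float:
    """Margin contrastive loss for one pair at embedding distance d."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if label == "similar":
        return float(d**2)
    if label == "dissimilar":
        return float(max(0.0, margin - d) ** 2)
    raise ValueError(f"unknown label {label!r}")


# ----------------------------------------------------------------------
# pair sampling
# ----------------------------------------------------------------------

def _sample_coord_pairs(sequences: Sequence[PoseSequence],
                        config: TrainingConfig, rng: np.random.Generator,
                        n_pairs: int):
    """Balanced coordinate-level pair batch.

    Returns (coords_a, coords_b, similar_mask) with coords (P, 25, 2).
    """
    if not sequences:
        raise ValueError("at least one pose sequence is required")
    n_sim = n_pairs // 2
    n_dis = n_pairs - n_sim
    coords = [s.coords for s in sequences]
    ca, cb, sim = [], [], []
    for _ in range(n_sim):
        si = rng.integers(len(coords))
        fi = rng.integers(len(coords[si]))
        base = coords[si][fi]
        jit = base + rng.normal(0.0, config.jitter_scale, base.shape) \
            if config.jitter_scale > 0 else base.copy()
        ca.append(base)
        cb.append(jit)
        sim.append(True)
    for _ in range(n_dis):
        if len(coords) >= 2:
            si, sj = rng.choice(len(coords), size=2, replace=False)
            fi = rng.integers(len(coords[si]))
            fj = rng.integers(len(coords[sj]))
            ca.append(coords[si][fi])
            cb.append(coords[sj][fj])
        else:
            si = 0
            L = len(coords[0])
            period = config.period_hint or float(L)
            quarter = max(1, int(round(period / 4)))
            fi = rng.integers(L)
            # pick a frame whose phase differs by [1/4, 3/4] of a period
            delta = int(rng.integers(quarter, max(quarter + 1, 3 * quarter)))
            fj = (fi + delta) % L
            ca.append(coords[si][fi])
            cb.append(coords[si][fj])
        sim.append(False)
    return np.stack(ca), np.stack(cb), np.asarray(sim)


def sample_pairs(sequences: Sequence[PoseSequence], config: TrainingConfig,
                 rng: np.random.Generator, n_pairs: int,
                 mode: str = "2D") -> List[TrainingPair]:
    """Balanced list of labelled training pairs as skeleton graphs."""
    from .pose_io import PoseFrame

    ca, cb, sim = _sample_coord_pairs(sequences, config, rng, n_pairs)
    pairs = []
    for k in range(len(sim)):
        fa = PoseFrame(0, np.column_stack([ca[k], np.ones(N_JOINTS)]))
        fb = PoseFrame(0, np.column_stack([cb[k], np.ones(N_JOINTS)]))
        pairs.append(TrainingPair(
            frame_to_graph(fa, mode), frame_to_graph(fb, mode),
            "similar" if sim[k] else "dissimilar",
        ))
    return pairs


# ----------------------------------------------------------------------
# optimisation
# ----------------------------------------------------------------------

class _Adam:
    def __init__(self, params: ModelParams, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: ModelParams, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_loss(params_t, mconfig: ModelConfig, ca, cb, sim_mask,
                margin: float):
    """Scalar loss Tensor for a coordinate pair batch."""
    P = ca.shape[0]
    if mconfig.model_type == "GEM":
        stacked = np.concatenate([ca, cb])
        gfs = embed_frames(stacked, params_t, mconfig)
        ga = ad.gather(gfs, np.arange(P))
        gb = ad.gather(gfs, np.arange(P, 2 * P))
    else:
        ga, gb = embed_frame_pairs(ca, cb, params_t, mconfig)
    diff = ga - gb
    d = ad.sqrt(ad.tsum(diff * diff, axis=1) + 1e-12)
    sim = sim_mask.astype(np.float64)
    loss_sim = sim * d * d
    hinge = ad.relu(margin - d)
    loss_dis = (1.0 - sim) * hinge * hinge
    return (loss_sim + loss_dis).sum() / float(P)


def train(model_type: str, mode: str, sequences: Sequence[PoseSequence],
          config: TrainingConfig,
          model_config: Optional[ModelConfig] = None
          ) -> Tuple[ModelParams, np.ndarray]:
    """Train embedding parameters; returns (params, per-iteration loss).

    Deterministic given ``config.seed`` (which also seeds the weight
    initialisation unless an explicit model_config is supplied).
    """
    if model_config is None:
        model_config = ModelConfig(mode=mode, model_type=model_type,
                                   seed=config.seed)
    else:
        if model_config.mode != mode or model_config.model_type != model_type:
            from dataclasses import replace
            model_config = replace(model_config, mode=mode,
                                   model_type=model_type)
    params = init_params(model_config)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(params, config.learning_rate)
    losses = np.empty(config.iterations)
    for it in range(config.iterations):
        ca, cb, sim = _sample_coord_pairs(sequences, config, rng,
                                          config.batch_pairs)
        params_t = {k: ad.Tensor(v) for k, v in params.items()}
        loss = _batch_loss(params_t, model_config, ca, cb, sim,
                           config.margin)
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise TrainingDiverged(
                f"non-finite loss {lval} at iteration {it}; try a lower "
                f"learning rate (current {config.learning_rate})"
            )
        losses[it] = lval
        loss.backward()
        grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.data))
                 for k, t in params_t.items()}
        opt.step(params, grads)
    return params, losses
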