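"""Graph-embedding model (GEM) for skeleton frames.

Pipeline per frame: encode node and edge features with small MLPs, run T
rounds of intra-graph message passing along the body25 edges, then
aggregate node states into one fixed-dimension graph vector with a
gated (logistic-sigmoid) sum followed by a final MLP.  Comparing two
rowers framewise then reduces to Euclidean distances between their
graph vectors.

Message passing: every undirected edge carries two directed messages,
``Value(j->i) = f_value(h_i, h_j, e_ij)``; each node sums its incoming
messages and updates through ``f_node`` (a GRU cell by default, an MLP
core optionally).  Node-index summation order is fixed, so results are
bit-reproducible for a given seed and configuration.

The forward code runs on plain ndarrays for inference and on autodiff
Tensors for training (the parameter dict decides which).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .pose_io import MODES, N_JOINTS, PoseSequence, SkeletonGraph, body25_edges

__all__ = [
    "ModelConfig",
    "ModelParams",
    "NodeStates",
    "GraphVector",
    "ConfigurationError",
    "init_params",
    "encode",
    "propagate",
    "aggregate",
    "embed_sequence",
    "embed_frames",
    "mode_features",
    "save_checkpoint",
    "load_checkpoint",
]

ModelParams = Dict[str, np.ndarray]


class ConfigurationError(ValueError):
    """Parameter shapes inconsistent with the model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration shared by GEM and GMN.

    ``input_scale`` is a fixed conditioning constant (pixels) dividing
    raw coordinates before the encoder; it is identical for every rower,
    so it rescales all pairwise distances by the same monotone factor
    and leaves rankings untouched.
    """

    mode: str = "2D"
    model_type: str = "GEM"            # "GEM" or "GMN"
    node_state_dim: int = 32
    graph_vector_dim: int = 128
    rounds: int = 5                    # T rounds of message passing
    message_net_depth: int = 1         # hidden layers in f_value
    update_core: str = "GRU"           # "GRU" or "MLP"
    input_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.model_type not in ("GEM", "GMN"):
            raise ConfigurationError(f"unknown model type {self.model_type!r}")
        if self.update_core not in ("GRU", "MLP"):
            raise ConfigurationError(f"unknown update core {self.update_core!r}")
        if self.node_state_dim < 1 or self.graph_vector_dim < 1:
            raise ConfigurationError("dimensions must be >= 1")
        if self.rounds < 0:
            raise ConfigurationError("rounds must be >= 0")

    @property
    def in_dim(self) -> int:
        return 2 if self.mode == "2D" else 1

    @property
    def core_in_dim(self) -> int:
        # GMN cores consume the intra-graph message sum plus the
        # cross-graph difference vector
        h = self.node_state_dim
        return 2 * h if self.model_type == "GMN" else h


@dataclass
class NodeStates:
    """Per-node hidden states of one skeleton graph at some round t."""

    h: np.ndarray      # (25, node_state_dim)
    round: int = 0


@dataclass
class GraphVector:
    """Fixed-dimension embedding of one frame's skeleton graph."""

    gf: np.ndarray
    frame_index: int = 0


# ----------------------------------------------------------------------
# parameter initialisation
# ----------------------------------------------------------------------

def _init_mlp(params, rng, name, dims):
    for i, (fan_in, fan_out) in enumerate(zip(dims, dims[1:])):
        lim = 1.0 / np.sqrt(fan_in)
        params[f"{name}_W{i}"] = rng.uniform(-lim, lim, (fan_in, fan_out))
        params[f"{name}_b{i}"] = np.zeros(fan_out)


def init_params(config: ModelConfig) -> ModelParams:
    """Seeded scaled-uniform initialisation of all weight arrays."""
    rng = np.random.default_rng(config.seed)
    h, g = config.node_state_dim, config.graph_vector_dim
    params: ModelParams = {}
    _init_mlp(params, rng, "enc_node", [config.in_dim, h, h])
    _init_mlp(params, rng, "enc_edge", [1, h, h])
    msg_dims = [3 * h] + [2 * h] * config.message_net_depth + [h]
    _init_mlp(params, rng, "msg", msg_dims)
    m = config.core_in_dim
    if config.update_core == "GRU":
        for gate in ("z", "r", "n"):
            lim = 1.0 / np.sqrt(m + h)
            params[f"gru_W{gate}"] = rng.uniform(-lim, lim, (m + h, h))
            params[f"gru_b{gate}"] = np.zeros(h)
    else:
        _init_mlp(params, rng, "core", [m + h, h, h])
    _init_mlp(params, rng, "agg_gate", [h, g])
    _init_mlp(params, rng, "agg_trans", [h, g])
    _init_mlp(params, rng, "agg_out", [g, g, g])
    return params


def mlp_apply(params, name: str, x):
    """Apply the named MLP: affine layers with ReLU between (linear output)."""
    i = 0
    out = x
    while f"{name}_W{i}" in params:
        if i > 0:
            out = ad.relu(out)
        out = out @ params[f"{name}_W{i}"] + params[f"{name}_b{i}"]
        i += 1
    if i == 0:
        raise ConfigurationError(f"no parameters found for MLP {name!r}")
    return out


def core_update(params, config: ModelConfig, h_prev, msg_in):
    """f_node: combine previous state with the summed incoming messages."""
    x = ad.concat([msg_in, h_prev], axis=-1)
    if config.update_core == "GRU":
        z = ad.sigmoid(x @ params["gru_Wz"] + params["gru_bz"])
        r = ad.sigmoid(x @ params["gru_Wr"] + params["gru_br"])
        xn = ad.concat([msg_in, r * h_prev], axis=-1)
        n = ad.tanh(xn @ params["gru_Wn"] + params["gru_bn"])
        return (1.0 - z) * h_prev + z * n
    return mlp_apply(params, "core", x)


# ----------------------------------------------------------------------
# batched internals (graphs flattened along axis 0)
# ----------------------------------------------------------------------

_EDGES = np.array(body25_edges(), dtype=np.intp)


def directed_edges(n_graphs: int, n_nodes: int = N_JOINTS):
    """Directed (src, dst) index arrays for ``n_graphs`` stacked skeletons."""
    offs = (np.arange(n_graphs, dtype=np.intp) * n_nodes)[:, None]
    a = (_EDGES[:, 0][None, :] + offs).ravel()
    b = (_EDGES[:, 1][None, :] + offs).ravel()
    # each undirected edge contributes a->b and b->a
    src = np.concatenate([a, b])
    dst = np.concatenate([b, a])
    return src, dst


def encode_nodes(params, config: ModelConfig, feats):
    """h^0 for flattened node features (N, in_dim), scaled to unit order."""
    return mlp_apply(params, "enc_node", feats / config.input_scale)


def encode_edges(params, n_directed: int):
    """Encodings for the constant-1 edge features, tiled per directed edge."""
    one = np.ones((1, 1))
    enc = mlp_apply(params, "enc_edge", one)
    if isinstance(enc, ad.Tensor):
        return ad.gather(enc, np.zeros(n_directed, dtype=np.intp))
    return np.broadcast_to(enc, (n_directed, enc.shape[1]))


def propagate_rounds(params, config, h, src, dst, e_dir, rounds,
                     cross_fn=None):
    """Run ``rounds`` of message passing over flattened node states."""
    n = h.shape[0] if not isinstance(h, ad.Tensor) else h.data.shape[0]
    for _ in range(rounds):
        hi = ad.gather(h, dst)
        hj = ad.gather(h, src)
        vals = mlp_apply(params, "msg", ad.concat([hi, hj, e_dir], axis=-1))
        msum = ad.segment_sum(vals, dst, n)
        if cross_fn is not None:
            msum = ad.concat([msum, cross_fn(h)], axis=-1)
        h = core_update(params, config, h, msum)
    return h


def aggregate_nodes(params, h, graph_idx, n_graphs: int):
    """Gated permutation-invariant sum per graph, then the output MLP."""
    gate = ad.sigmoid(mlp_apply(params, "agg_gate", h))
    trans = mlp_apply(params, "agg_trans", h)
    pooled = ad.segment_sum(gate * trans, graph_idx, n_graphs)
    return mlp_apply(params, "agg_out", pooled)


def mode_features(coords_xy: np.ndarray, mode: str) -> np.ndarray:
    """Select node features from (..., 25, 2) raw coordinates."""
    if mode == "1D-X":
        return coords_xy[..., :1]
    if mode == "1D-Y":
        return coords_xy[..., 1:2]
    if mode == "2D":
        return coords_xy
    raise ConfigurationError(f"unknown mode {mode!r}")


def embed_frames(coords_xy: np.ndarray, params: ModelParams,
                 config: ModelConfig):
    """Embed a stack of frames: (F, 25, 2) raw coordinates -> (F, g)."""
    F = coords_xy.shape[0]
    feats = mode_features(coords_xy, config.mode).reshape(F * N_JOINTS, -1)
    _check_dims(params, config, feats.shape[1])
    h = encode_nodes(params, config, feats)
    src, dst = directed_edges(F)
    e_dir = encode_edges(params, len(src))
    h = propagate_rounds(params, config, h, src, dst, e_dir, config.rounds)
    graph_idx = np.repeat(np.arange(F, dtype=np.intp), N_JOINTS)
    return aggregate_nodes(params, h, graph_idx, F)


def _check_dims(params, config, in_dim):
    W = params["enc_node_W0"]
    W = W.data if isinstance(W, ad.Tensor) else W
    if W.shape[0] != in_dim:
        raise ConfigurationError(
            f"encoder expects input dim {W.shape[0]}, graph provides {in_dim}"
        )
    if W.shape[1] != config.node_state_dim:
        raise ConfigurationError("parameter shapes do not match config")


# ----------------------------------------------------------------------
# public single-graph operations
# ----------------------------------------------------------------------

def encode(graph: SkeletonGraph, params: ModelParams,
           config: ModelConfig) -> Tuple[NodeStates, np.ndarray]:
    """Round-0 node states and per-undirected-edge encodings (Eq-style
    feature encoding of nodes and constant-1 edges)."""
    _check_dims(params, config, graph.node_features.shape[1])
    h0 = encode_nodes(params, config, graph.node_features)
    e_enc = mlp_apply(params, "enc_edge", graph.edge_features)
    return NodeStates(h=np.asarray(h0), round=0), np.asarray(e_enc)


def propagate(states: NodeStates, edges: np.ndarray,
              edge_encodings: np.ndarray, params: ModelParams,
              config: ModelConfig, rounds: Optional[int] = None) -> NodeStates:
    """Run T rounds of intra-graph message passing on one skeleton.

    Every undirected edge expands to two directed messages; a node's
    update consumes the sum of its incoming messages.  ``rounds=0``
    returns the states unchanged.
    """
    T = config.rounds if rounds is None else rounds
    if T < 0:
        raise ValueError("rounds must be >= 0")
    h = np.asarray(states.h, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.intp)
    if edges.size == 0:
        src = dst = np.zeros(0, dtype=np.intp)
        e_dir = np.zeros((0, h.shape[1]))
    else:
        src = np.concatenate([edges[:, 0], edges[:, 1]])
        dst = np.concatenate([edges[:, 1], edges[:, 0]])
        e_dir = np.concatenate([edge_encodings, edge_encodings], axis=0)
    for _ in range(T):
        if len(src):
            hi, hj = h[dst], h[src]
            vals = mlp_apply(params, "msg",
                             np.concatenate([hi, hj, e_dir], axis=-1))
            msum = ad.segment_sum(vals, dst, h.shape[0])
        else:
            msum = np.zeros_like(h)
        if config.model_type == "GMN":
            # intra-only propagation of a GMN: zero cross message
            msum = np.concatenate([msum, np.zeros_like(h)], axis=-1)
        h = core_update(params, config, h, msum)
    return NodeStates(h=h, round=states.round + T)


def aggregate(states: NodeStates, params: ModelParams,
              frame_index: int = 0) -> GraphVector:
    """Gated sum over nodes followed by the output MLP -> graph vector."""
    h = np.asarray(states.h, dtype=np.float64)
    idx = np.zeros(h.shape[0], dtype=np.intp)
    gf = aggregate_nodes(params, h, idx, 1)
    return GraphVector(gf=np.asarray(gf)[0], frame_index=frame_index)


def embed_sequence(seq: PoseSequence, mode: str, params: ModelParams,
                   config: ModelConfig) -> List[GraphVector]:
    """One graph vector per frame, in frame order (deterministic)."""
    if mode != config.mode:
        config = replace(config, mode=mode)
    gfs = embed_frames(seq.coords, params, config)
    return [GraphVector(gf=np.asarray(gfs)[i], frame_index=f.index)
            for i, f in enumerate(seq.frames)]


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, params: ModelParams, config: ModelConfig) -> None:
    """Serialise config + weights as JSON (text, exact float round-trip)."""
    payload = {
        "format": "rowgraph-checkpoint-1",
        "config": asdict(config),
        "params": {k: v.tolist() for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> Tuple[ModelParams, ModelConfig]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "rowgraph-checkpoint-1":
        raise ValueError(f"{path} is not a rowgraph checkpoint")
    config = ModelConfig(**payload["config"])
    params = {k: np.asarray(v, dtype=np.float64)
              for k, v in payload["params"].items()}
    return params, config
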