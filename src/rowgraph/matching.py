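"""Graph-matching network (GMN): joint embedding of a skeleton-graph pair.

The GMN shares the GEM's encoder, message net, update core and
aggregator, but every propagation round additionally exchanges
cross-graph messages: each node i of one graph attends over all 25 nodes
j of the other graph with softmax weights

    a(j->i) = exp(s_h(h_i, h_j)) / sum_j' exp(s_h(h_i, h_j')),

where s_h is the NEGATIVE squared Euclidean distance between states, so
attention concentrates on the closest counterpart node.  The summed
cross message has the closed form

    sum_j mu(j->i) = h_i - sum_j a(j->i) h_j,

i.e. the difference between h_i and its (soft) nearest neighbour in the
other graph.  Because of this coupling, a graph's embedding depends on
its comparison partner; embedding a graph against itself yields two
identical vectors and distance exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from . import autodiff as ad
from .graph_model import (
    ConfigurationError,
    GraphVector,
    ModelConfig,
    ModelParams,
    NodeStates,
    aggregate_nodes,
    core_update,
    directed_edges,
    encode_edges,
    encode_nodes,
    mlp_apply,
    mode_features,
    _check_dims,
)
from .pose_io import N_JOINTS, PoseSequence, SkeletonGraph

__all__ = [
    "CrossGraphState",
    "cross_attention",
    "cross_sum",
    "gmn_update",
    "embed_pair",
    "embed_frame_pairs",
    "embed_pair_sequences",
]


@dataclass
class CrossGraphState:
    """Attention weights and node states of a graph pair at one round.

    ``attn_12[i, j]`` is the weight a(j->i) of graph-1 node i over
    graph-2 node j; rows are probability distributions.  ``attn_21`` is
    the reverse direction.
    """

    states1: np.ndarray   # (25, h)
    states2: np.ndarray   # (25, h)
    attn_12: np.ndarray   # (25, 25)
    attn_21: np.ndarray   # (25, 25)


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    shift = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shift)
    return e / e.sum(axis=-1, keepdims=True)


def cross_attention(states1: NodeStates, states2: NodeStates) -> CrossGraphState:
    """Per-node softmax attention of each graph over the other's nodes."""
    h1 = np.asarray(states1.h, dtype=np.float64)
    h2 = np.asarray(states2.h, dtype=np.float64)
    if h1.shape[1] != h2.shape[1]:
        raise ConfigurationError(
            f"state dims differ: {h1.shape[1]} vs {h2.shape[1]}"
        )
    # s_h = negative squared Euclidean distance; einsum keeps the score
    # matrix bitwise symmetric when the two graphs are identical
    dots = np.einsum("ik,jk->ij", h1, h2)
    d2 = ((h1**2).sum(axis=1)[:, None] + (h2**2).sum(axis=1)[None, :]
          - 2.0 * dots)
    attn_12 = _softmax_rows(-d2)
    attn_21 = _softmax_rows(np.ascontiguousarray(-d2.T))
    return CrossGraphState(h1, h2, attn_12, attn_21)


def cross_sum(state: CrossGraphState, node: int, graph: int = 1) -> np.ndarray:
    """Summed cross message for one node, by explicit summation of
    mu(j->i) = a(j->i) (h_i - h_j); equals h_i - sum_j a(j->i) h_j."""
    if graph == 1:
        h_i, other, a = state.states1[node], state.states2, state.attn_12[node]
    else:
        h_i, other, a = state.states2[node], state.states1, state.attn_21[node]
    mu = a[:, None] * (h_i[None, :] - other)
    return mu.sum(axis=0)


# ----------------------------------------------------------------------
# joint propagation
# ----------------------------------------------------------------------

def _batched_cross(h_flat, n_pairs: int, hdim: int):
    """Closed-form summed cross messages for flattened pair states.

    ``h_flat`` stacks graph-1 nodes of all pairs first, then graph-2
    nodes: shape (2 * n_pairs * 25, h).  Returns the matching stack of
    cross vectors h_i - sum_j a(j->i) h_j.
    """
    half = n_pairs * N_JOINTS
    H1 = ad.reshape(ad.gather(h_flat, np.arange(half)),
                    (n_pairs, N_JOINTS, hdim))
    H2 = ad.reshape(ad.gather(h_flat, np.arange(half, 2 * half)),
                    (n_pairs, N_JOINTS, hdim))
    n1 = ad.tsum(H1 * H1, axis=-1, keepdims=True)        # (P, 25, 1)
    n2 = ad.tsum(H2 * H2, axis=-1, keepdims=True)
    if isinstance(h_flat, ad.Tensor):
        dots = H1 @ ad.swapaxes(H2, -1, -2)              # (P, 25, 25)
    else:
        # einsum sums over k in index order, so dots is bitwise symmetric
        # for identical graphs (BLAS matmul is not); this keeps
        # embed-against-self distances exactly zero on the inference path
        dots = np.einsum("fik,fjk->fij", H1, H2)
    # sum the norms first: float addition commutes, subtraction does not
    norms = n1 + ad.swapaxes(n2, -1, -2)
    scores = 2.0 * dots - norms                          # -squared distance
    a12 = ad.softmax_lastaxis(scores)
    scores_t = ad.swapaxes(scores, -1, -2)
    if not isinstance(scores_t, ad.Tensor):
        # contiguous copy so the softmax row sums reduce in the same
        # order as a12's (pairwise summation is layout-dependent)
        scores_t = np.ascontiguousarray(scores_t)
    a21 = ad.softmax_lastaxis(scores_t)
    cross1 = H1 - a12 @ H2
    cross2 = H2 - a21 @ H1
    return ad.concat(
        [ad.reshape(cross1, (half, hdim)), ad.reshape(cross2, (half, hdim))],
        axis=0,
    )


def embed_frame_pairs(coords1: np.ndarray, coords2: np.ndarray,
                      params: ModelParams, config: ModelConfig):
    """Jointly embed F frame pairs: two (F, 25, 2) stacks -> two (F, g).

    Intra-graph messages run over each graph's own body25 edges (the two
    graphs share the topology); cross messages couple partner frames.
    """
    if config.model_type != "GMN":
        raise ConfigurationError("embed_frame_pairs requires a GMN config")
    if coords1.shape != coords2.shape:
        raise ValueError("frame stacks must have equal shape")
    F = coords1.shape[0]
    hdim = config.node_state_dim
    feats = np.concatenate([
        mode_features(coords1, config.mode).reshape(F * N_JOINTS, -1),
        mode_features(coords2, config.mode).reshape(F * N_JOINTS, -1),
    ])
    _check_dims(params, config, feats.shape[1])
    h = encode_nodes(params, config, feats)
    src, dst = directed_edges(2 * F)
    e_dir = encode_edges(params, len(src))
    n = 2 * F * N_JOINTS
    for _ in range(config.rounds):
        hi = ad.gather(h, dst)
        hj = ad.gather(h, src)
        vals = mlp_apply(params, "msg", ad.concat([hi, hj, e_dir], axis=-1))
        msum = ad.segment_sum(vals, dst, n)
        cross = _batched_cross(h, F, hdim)
        h = core_update(params, config, h,
                        ad.concat([msum, cross], axis=-1))
    graph_idx = np.repeat(np.arange(2 * F, dtype=np.intp), N_JOINTS)
    gfs = aggregate_nodes(params, h, graph_idx, 2 * F)
    if isinstance(gfs, ad.Tensor):
        g1 = ad.gather(gfs, np.arange(F))
        g2 = ad.gather(gfs, np.arange(F, 2 * F))
        return g1, g2
    return gfs[:F], gfs[F:]


def gmn_update(states1: NodeStates, states2: NodeStates,
               edge_encodings: np.ndarray, params: ModelParams,
               config: ModelConfig,
               cross_scale: float = 1.0) -> Tuple[NodeStates, NodeStates]:
    """One joint propagation round applied simultaneously to both graphs.

    ``cross_scale=0`` forces the cross message to zero, reducing the
    round to plain intra-graph propagation (a degenerate-case check).
    """
    h1 = np.asarray(states1.h, dtype=np.float64)
    h2 = np.asarray(states2.h, dtype=np.float64)
    new1, new2 = _joint_round(h1, h2, edge_encodings, params, config,
                              cross_scale)
    return (
        NodeStates(h=new1, round=states1.round + 1),
        NodeStates(h=new2, round=states2.round + 1),
    )


def _joint_round(h1: np.ndarray, h2: np.ndarray, edge_encodings,
                 params: ModelParams, config: ModelConfig,
                 cross_scale: float = 1.0):
    h = np.concatenate([h1, h2])
    src, dst = directed_edges(2)
    # per-undirected-edge encodings, tiled over both graphs and directions
    e_und = np.asarray(edge_encodings)
    e_dir = np.concatenate([e_und, e_und, e_und, e_und], axis=0)
    hi, hj = h[dst], h[src]
    vals = mlp_apply(params, "msg", np.concatenate([hi, hj, e_dir], axis=-1))
    msum = ad.segment_sum(vals, dst, h.shape[0])
    state = cross_attention(NodeStates(h1), NodeStates(h2))
    cross1 = h1 - state.attn_12 @ h2
    cross2 = h2 - state.attn_21 @ h1
    cross = cross_scale * np.concatenate([cross1, cross2])
    new = core_update(params, config, h,
                      np.concatenate([msum, cross], axis=-1))
    return new[:N_JOINTS], new[N_JOINTS:]


def embed_pair(g1: SkeletonGraph, g2: SkeletonGraph, params: ModelParams,
               config: ModelConfig) -> Tuple[GraphVector, GraphVector]:
    """T joint rounds on a graph pair, then independent aggregation.

    ``embed_pair(g, g)`` returns two identical vectors (distance 0), and
    swapping the arguments swaps the outputs exactly.
    """
    if g1.mode != g2.mode:
        raise ValueError("both graphs must share the input mode")
    gfs1, gfs2 = embed_frame_pairs(
        _graph_coords(g1)[None], _graph_coords(g2)[None], params, config
    )
    return (
        GraphVector(gf=np.asarray(gfs1)[0]),
        GraphVector(gf=np.asarray(gfs2)[0]),
    )


def _graph_coords(g: SkeletonGraph) -> np.ndarray:
    """Recover a (25, 2) coordinate array view of a graph's features.

    1D graphs are lifted by placing the single coordinate in the column
    ``mode_features`` will select again, zero elsewhere.
    """
    if g.mode == "2D":
        return g.node_features
    xy = np.zeros((N_JOINTS, 2))
    col = 0 if g.mode == "1D-X" else 1
    xy[:, col] = g.node_features[:, 0]
    return xy


def embed_pair_sequences(seq1: PoseSequence, seq2: PoseSequence,
                         params: ModelParams, config: ModelConfig,
                         start1: int = 0, start2: int = 0,
                         length: int | None = None
                         ) -> Tuple[List[GraphVector], List[GraphVector]]:
    """Framewise joint embedding of two aligned sequences (GMN path)."""
    c1 = seq1.coords[start1:]
    c2 = seq2.coords[start2:]
    L = min(len(c1), len(c2)) if length is None else length
    if L < 1:
        raise ValueError("sequences do not overlap")
    g1, g2 = embed_frame_pairs(c1[:L], c2[:L], params, config)
    g1, g2 = np.asarray(g1), np.asarray(g2)
    return (
        [GraphVector(gf=g1[i], frame_index=start1 + i) for i in range(L)],
        [GraphVector(gf=g2[i], frame_index=start2 + i) for i in range(L)],
    )
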