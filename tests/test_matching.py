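"""Cross-graph attention and joint pair embedding of the GMN."""

import numpy as np
import pytest

import rowgraph as rg
from rowgraph import matching
from rowgraph.graph_model import NodeStates, encode, propagate
from rowgraph.matching import (
    cross_attention,
    cross_sum,
    embed_frame_pairs,
    embed_pair,
    gmn_update,
)
from rowgraph.pose_io import frame_to_graph

RNG = np.random.default_rng(123)


def random_states(n=25, dim=8):
    return NodeStates(h=RNG.normal(size=(n, dim)))


class TestCrossAttention:
    def test_rows_are_probability_distributions(self):
        for _ in range(5):
            st = cross_attention(random_states(), random_states())
            for a in (st.attn_12, st.attn_21):
                assert np.all(a >= 0)
                np.testing.assert_allclose(a.sum(axis=1), 1.0, rtol=1e-12)

    def test_equidistant_nodes_get_equal_weight(self):
        s1 = NodeStates(h=np.array([[2.0]]))
        s2 = NodeStates(h=np.array([[1.0], [3.0]]))     # both at distance 1
        st = cross_attention(s1, s2)
        np.testing.assert_allclose(st.attn_12[0], [0.5, 0.5])

    def test_identical_graphs_attend_to_own_counterpart(self):
        s = random_states()
        st = cross_attention(s, NodeStates(h=s.h.copy()))
        assert np.array_equal(st.attn_12.argmax(axis=1), np.arange(25))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(Exception, match="dim"):
            cross_attention(random_states(dim=4), random_states(dim=8))


class TestCrossSum:
    def test_identity_sum_mu_equals_closed_form(self):
        """sum_j mu(j->i) == h_i - sum_j a(j->i) h_j on random states."""
        for _ in range(100):
            s1, s2 = random_states(), random_states()
            st = cross_attention(s1, s2)
            i = int(RNG.integers(25))
            explicit = cross_sum(st, i, graph=1)
            closed = st.states1[i] - st.attn_12[i] @ st.states2
            np.testing.assert_allclose(explicit, closed, rtol=1e-9,
                                       atol=1e-12)

    def test_identical_graphs_near_one_self_attention_gives_zero(self):
        # widely separated states => softmax ~ 1 on the self-counterpart
        h = (np.arange(25)[:, None] * 100.0) * np.ones((25, 4))
        st = cross_attention(NodeStates(h=h), NodeStates(h=h.copy()))
        for i in (0, 12, 24):
            np.testing.assert_allclose(cross_sum(st, i), 0.0, atol=1e-8)

    def test_one_dim_toy_hand_arithmetic(self):
        """h_i = 2 against nodes (1, 3): equal weights, sum = 2 - 2 = 0."""
        st = cross_attention(NodeStates(h=np.array([[2.0]])),
                             NodeStates(h=np.array([[1.0], [3.0]])))
        np.testing.assert_allclose(cross_sum(st, 0), 0.0, atol=1e-15)


class TestGmnUpdate:
    def test_forced_zero_cross_reduces_to_gem_propagate(self, small_gmn,
                                                        short_seq):
        """cross_scale=0 turns a joint round into intra-graph propagation."""
        params, config = small_gmn
        ga = frame_to_graph(short_seq.frames[0], "2D")
        gb = frame_to_graph(short_seq.frames[30], "2D")
        sa, e_enc = encode(ga, params, config)
        sb, _ = encode(gb, params, config)
        intra_a = propagate(sa, ga.edges, e_enc, params, config, rounds=1)
        intra_b = propagate(sb, gb.edges, e_enc, params, config, rounds=1)
        out1, out2 = gmn_update(sa, sb, e_enc, params, config, cross_scale=0.0)
        np.testing.assert_allclose(out1.h, intra_a.h, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(out2.h, intra_b.h, rtol=1e-9, atol=1e-12)

    def test_swapping_inputs_swaps_outputs_exactly(self, small_gmn,
                                                   short_seq):
        params, config = small_gmn
        ga = frame_to_graph(short_seq.frames[0], "2D")
        gb = frame_to_graph(short_seq.frames[30], "2D")
        sa, e_enc = encode(ga, params, config)
        sb, _ = encode(gb, params, config)
        a1, a2 = gmn_update(sa, sb, e_enc, params, config)
        b1, b2 = gmn_update(NodeStates(h=sb.h.copy()),
                            NodeStates(h=sa.h.copy()), e_enc, params, config)
        np.testing.assert_array_equal(a1.h, b2.h)
        np.testing.assert_array_equal(a2.h, b1.h)

    def test_one_round_matches_hand_unrolled_oracle(self, small_gmn,
                                                    short_seq):
        """One joint round on a real pair, recomputed with explicit loops
        over directed edges and the closed-form cross term."""
        params, config = small_gmn
        ga = frame_to_graph(short_seq.frames[0], "2D")
        gb = frame_to_graph(short_seq.frames[25], "2D")
        sa, e_enc = encode(ga, params, config)
        sb, _ = encode(gb, params, config)
        out1, out2 = gmn_update(sa, sb, e_enc, params, config)

        def mlp(name, x):
            i, v = 0, x
            while f"{name}_W{i}" in params:
                if i:
                    v = np.maximum(v, 0)
                v = v @ params[f"{name}_W{i}"] + params[f"{name}_b{i}"]
                i += 1
            return v

        def gru(x, hprev):
            cat = np.concatenate([x, hprev])
            z = 1 / (1 + np.exp(-(cat @ params["gru_Wz"] + params["gru_bz"])))
            r = 1 / (1 + np.exp(-(cat @ params["gru_Wr"] + params["gru_br"])))
            catn = np.concatenate([x, r * hprev])
            n = np.tanh(catn @ params["gru_Wn"] + params["gru_bn"])
            return (1 - z) * hprev + z * n

        st = cross_attention(sa, sb)
        edges = [tuple(e) for e in ga.edges]
        for h_self, h_other, attn, expected in (
            (sa.h, sb.h, st.attn_12, out1.h),
            (sb.h, sa.h, st.attn_21, out2.h),
        ):
            for i in range(25):
                msum = np.zeros(config.node_state_dim)
                for k, (a, b) in enumerate(edges):
                    if b == i:
                        msum += mlp("msg", np.concatenate(
                            [h_self[i], h_self[a], e_enc[k]]))
                    if a == i:
                        msum += mlp("msg", np.concatenate(
                            [h_self[i], h_self[b], e_enc[k]]))
                cross = h_self[i] - attn[i] @ h_other
                upd = gru(np.concatenate([msum, cross]), h_self[i])
                np.testing.assert_allclose(expected[i], upd, rtol=1e-8,
                                           atol=1e-10)


class TestEmbedPair:
    def test_identical_inputs_distance_exactly_zero(self, small_gmn,
                                                    short_seq):
        params, config = small_gmn
        g = frame_to_graph(short_seq.frames[5], "2D")
        v1, v2 = embed_pair(g, g, params, config)
        assert np.array_equal(v1.gf, v2.gf)

    def test_swap_symmetry_and_distance_symmetry(self, small_gmn, short_seq):
        params, config = small_gmn
        ga = frame_to_graph(short_seq.frames[0], "2D")
        gb = frame_to_graph(short_seq.frames[40], "2D")
        a1, a2 = embed_pair(ga, gb, params, config)
        b1, b2 = embed_pair(gb, ga, params, config)
        np.testing.assert_array_equal(a1.gf, b2.gf)
        np.testing.assert_array_equal(a2.gf, b1.gf)
        d_ab = np.linalg.norm(a1.gf - a2.gf)
        d_ba = np.linalg.norm(b1.gf - b2.gf)
        assert d_ab == d_ba

    def test_pair_embedding_differs_from_independent_gem(self, small_gmn,
                                                         short_seq):
        """The cross term makes the embedding partner-dependent."""
        params, config = small_gmn
        coords = short_seq.coords
        against_self, _ = embed_frame_pairs(coords[:1], coords[:1],
                                            params, config)
        against_other, _ = embed_frame_pairs(coords[:1], coords[40:41],
                                             params, config)
        assert np.linalg.norm(
            np.asarray(against_self) - np.asarray(against_other)) > 1e-8

    def test_mode_mismatch_raises(self, small_gmn, short_seq):
        params, config = small_gmn
        ga = frame_to_graph(short_seq.frames[0], "2D")
        gb = frame_to_graph(short_seq.frames[0], "1D-X")
        with pytest.raises(ValueError, match="mode"):
            embed_pair(ga, gb, params, config)

    def test_attention_rows_sum_to_one_at_every_round(self, small_gmn,
                                                      short_seq):
        """Track the joint rounds manually and check the distributions."""
        params, config = small_gmn
        ga = frame_to_graph(short_seq.frames[0], "2D")
        gb = frame_to_graph(short_seq.frames[30], "2D")
        sa, e_enc = encode(ga, params, config)
        sb, _ = encode(gb, params, config)
        for _ in range(config.rounds):
            st = cross_attention(sa, sb)
            np.testing.assert_allclose(st.attn_12.sum(axis=1), 1.0,
                                       rtol=1e-12)
            np.testing.assert_allclose(st.attn_21.sum(axis=1), 1.0,
                                       rtol=1e-12)
            # identity of the summed cross message at every round
            for i in (0, 7, 24):
                np.testing.assert_allclose(
                    cross_sum(st, i, graph=1),
                    st.states1[i] - st.attn_12[i] @ st.states2,
                    rtol=1e-9, atol=1e-12)
            sa, sb = gmn_update(sa, sb, e_enc, params, config)
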