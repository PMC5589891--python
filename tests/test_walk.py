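"""Signed similarities, the teleporting walk, and attachment probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srwa import (
    CommunitySet,
    ConvergenceError,
    SignedNetwork,
    WalkConfig,
    attachment_probabilities,
    build_walk_graph,
    jaccard_similarity,
    stationary_distribution,
)

# ---------------------------------------------------------------------------
# straight-line transcription of the attachment computation, used as an
# independent oracle: per hypothesis k, explicit node-level loops build the
# restricted Jaccard similarity matrix, the damped iteration runs to its
# fixed point from the normalised start vector, and the conditional, prior
# and total probabilities are combined term by term.
# ---------------------------------------------------------------------------


def attachment_oracle(net, communities, u, alpha=0.15):
    walk_nodes = []
    for c in communities:
        for v in sorted(c, key=str):
            if v not in walk_nodes:
                walk_nodes.append(v)
    m = len(walk_nodes)
    q = len(communities)
    restrict = set(walk_nodes) | {u}
    out = {}
    for sign in ("positive", "negative"):
        S = np.array(
            [
                [
                    jaccard_similarity(net, a, b, sign, restrict=restrict)
                    for b in walk_nodes
                ]
                for a in walk_nodes
            ]
        )
        s0_raw = np.array(
            [jaccard_similarity(net, v, u, sign, restrict=restrict) for v in walk_nodes]
        )
        priors = np.array(
            [
                np.mean(
                    [
                        jaccard_similarity(net, u, v, sign, restrict=restrict)
                        for v in c
                    ]
                )
                for c in communities
            ]
        )
        conds = np.zeros((q, q))
        if s0_raw.sum() > 0:
            M = np.zeros_like(S)
            for i in range(m):
                row = S[i].sum()
                M[i] = S[i] / row if row > 0 else np.full(m, 1.0 / m)
            for k, ck in enumerate(communities):
                d = np.array([1.0 / len(ck) if v in ck else 0.0 for v in walk_nodes])
                s = s0_raw / s0_raw.sum()
                for _ in range(20000):
                    nxt = (1 - alpha) * M.T @ s + alpha * d
                    if np.abs(nxt - s).sum() <= 1e-14:
                        break
                    s = nxt
                for j, cj in enumerate(communities):
                    conds[k, j] = np.mean([s[walk_nodes.index(v)] for v in cj])
        totals = np.array(
            [sum(conds[k, j] * priors[k] for k in range(q)) for j in range(q)]
        )
        out[sign] = (conds, priors, totals)
    return out


def grid_network():
    """Fixed 6-node, 2-community instance plus outside candidate 'u'."""
    net = SignedNetwork.from_edges(
        [
            ("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
            ("d", "e", 1), ("e", "f", 1), ("d", "f", 1),
            ("c", "d", -1), ("a", "e", -1),
            ("u", "a", 1), ("u", "b", 1), ("u", "f", -1),
        ]
    )
    comms = CommunitySet([{"a", "b", "c"}, {"d", "e", "f"}])
    return net, comms


class TestJaccard:
    def test_half_overlap(self):
        net = SignedNetwork.from_edges(
            [("vi", x, 1) for x in "abc"] + [("vj", x, 1) for x in "bcd"]
        )
        assert jaccard_similarity(net, "vi", "vj", "positive") == pytest.approx(0.5)

    def test_identical_neighbourhoods(self):
        net = SignedNetwork.from_edges(
            [("vi", x, 1) for x in "ab"] + [("vj", x, 1) for x in "ab"]
        )
        assert jaccard_similarity(net, "vi", "vj", "positive") == 1.0

    def test_empty_union_gives_zero(self):
        net = SignedNetwork.from_edges([("vi", "a", 1), ("vj", "b", 1)])
        assert jaccard_similarity(net, "vi", "vj", "negative") == 0.0
        assert jaccard_similarity(net, "a", "b", "positive") == 0.0

    def test_restriction_filters_neighbourhoods(self):
        net = SignedNetwork.from_edges(
            [("vi", x, 1) for x in "abc"] + [("vj", x, 1) for x in "bcd"]
        )
        assert jaccard_similarity(
            net, "vi", "vj", "positive", restrict={"b", "c"}
        ) == 1.0


class TestWalkGraph:
    def test_hypothesis_edges_attach_u_to_community_k(self):
        net, comms = grid_network()
        g = build_walk_graph(comms, net, "u", 0)
        assert set(g.walk_nodes) == {"a", "b", "c", "d", "e", "f"}
        assert g.m == 6
        for v in ("a", "b", "c"):
            assert frozenset(("u", v)) in g.positive_edges
        assert frozenset(("u", "d")) not in g.positive_edges

    def test_second_hypothesis_and_negative_edges(self):
        net, comms = grid_network()
        g = build_walk_graph(comms, net, "u", 1)
        for v in ("d", "e", "f"):
            assert frozenset(("u", v)) in g.positive_edges
        # u's observed negative edge into the walk set is retained
        assert frozenset(("u", "f")) in g.negative_edges

    def test_single_community_walks_over_its_members(self):
        net = SignedNetwork.from_edges([("a", "b", 1), ("u", "a", 1)])
        g = build_walk_graph(CommunitySet([{"a", "b"}]), net, "u", 0)
        assert set(g.walk_nodes) == {"a", "b"}

    def test_errors(self):
        net, comms = grid_network()
        with pytest.raises(IndexError):
            build_walk_graph(comms, net, "u", 5)
        with pytest.raises(RuntimeError):
            build_walk_graph(comms, net, "a", 0)


class TestStationaryDistribution:
    def test_single_state_is_certain(self):
        pi = stationary_distribution([[1.0]], [1.0], [1.0])
        assert pi == pytest.approx([1.0])

    def test_uniform_chain_has_uniform_fixed_point(self):
        m = 4
        M = np.full((m, m), 1 / m)
        pi = stationary_distribution(M, np.full(m, 1 / m), np.full(m, 1 / m))
        assert pi == pytest.approx(np.full(m, 1 / m))

    @given(seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_iteration_matches_direct_linear_solve(self, seed):
        rng = np.random.default_rng(seed)
        m = 3
        M = rng.random((m, m))
        M /= M.sum(axis=1, keepdims=True)
        s0 = rng.random(m)
        s0 /= s0.sum()
        d = rng.random(m)
        d /= d.sum()
        cfg = WalkConfig(alpha=0.15, tol=1e-12, max_iter=5000)
        pi = stationary_distribution(M, s0, d, cfg)
        direct = np.linalg.solve(np.eye(m) - 0.85 * M.T, 0.15 * d)
        assert np.abs(pi - direct).max() < 1e-8
        assert pi.sum() == pytest.approx(1.0)
        assert (pi >= 0.15 * d.min() - 1e-12).all()

    @given(seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_l1_contraction_by_one_minus_alpha(self, seed):
        rng = np.random.default_rng(seed)
        m = 4
        M = rng.random((m, m))
        M /= M.sum(axis=1, keepdims=True)
        d = np.full(m, 1 / m)
        a, b = rng.dirichlet(np.ones(m)), rng.dirichlet(np.ones(m))
        step = lambda s: 0.85 * M.T @ s + 0.15 * d
        assert np.abs(step(a) - step(b)).sum() <= 0.85 * np.abs(a - b).sum() + 1e-12

    def test_nonconvergence_raises_with_residual(self):
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ConvergenceError, match="residual"):
            stationary_distribution(
                M, [1.0, 0.0], [0.5, 0.5], WalkConfig(max_iter=1)
            )

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            stationary_distribution([[0.5, 0.2], [0.5, 0.5]], [1, 0], [0.5, 0.5])


class TestAttachmentProbabilities:
    def test_no_negative_edges_anywhere_zeroes_the_negative_branch(self):
        net = SignedNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("u", "a", 1), ("u", "b", 1), ("u", "c", 1)]
        )
        table = attachment_probabilities(CommunitySet([{"a", "b", "c"}]), net, "u")
        assert np.all(table.total_neg == 0.0)
        assert table.total_pos[0] > 0

    def test_symmetric_attachment_to_isomorphic_communities(self):
        net = SignedNetwork.from_edges(
            [("a1", "a2", 1), ("b1", "b2", 1), ("u", "a1", 1), ("u", "b1", 1)]
        )
        table = attachment_probabilities(
            CommunitySet([{"a1", "a2"}, {"b1", "b2"}]), net, "u"
        )
        assert table.total_pos[0] == pytest.approx(table.total_pos[1])

    def test_matches_straight_line_oracle_on_fixed_instance(self):
        net, comms = grid_network()
        table = attachment_probabilities(comms, net, "u")
        oracle = attachment_oracle(net, [set(c.members) for c in comms], "u")
        for got, want in (
            (table.total_pos, oracle["positive"][2]),
            (table.total_neg, oracle["negative"][2]),
            (table.prior_pos, oracle["positive"][1]),
            (table.prior_neg, oracle["negative"][1]),
            (table.conditional_pos, oracle["positive"][0]),
            (table.conditional_neg, oracle["negative"][0]),
        ):
            assert np.allclose(got, want, atol=1e-9)
        # the instance must actually discriminate: u leans to community 0
        assert table.total_pos[0] > table.total_pos[1]

    @given(seed=st.integers(0, 60))
    @settings(max_examples=12, deadline=None)
    def test_matches_oracle_on_random_instances(self, seed):
        from conftest import random_signed_network

        rng = np.random.default_rng(seed)
        net = random_signed_network(rng, n=9, p_edge=0.5)
        nodes = net.nodes
        comms = [set(nodes[0:3]), set(nodes[3:6])]
        u = nodes[6]
        table = attachment_probabilities(CommunitySet(comms), net, u)
        oracle = attachment_oracle(net, comms, u)
        assert np.allclose(table.total_pos, oracle["positive"][2], atol=1e-9)
        assert np.allclose(table.total_neg, oracle["negative"][2], atol=1e-9)

    def test_community_relabelling_permutes_totals(self):
        net, _ = grid_network()
        a = attachment_probabilities(
            CommunitySet([{"a", "b", "c"}, {"d", "e", "f"}]), net, "u"
        )
        b = attachment_probabilities(
            CommunitySet([{"d", "e", "f"}, {"a", "b", "c"}]), net, "u"
        )
        assert np.allclose(a.total_pos, b.total_pos[::-1])
        assert np.allclose(a.total_neg, b.total_neg[::-1])

    def test_positive_edge_to_every_member_raises_prior(self):
        """The hypothesis prior grows when u gains a positive link adjacent
        to all of the community's members."""
        net = SignedNetwork.from_edges(
            [("a", "b", 1), ("a", "c", 1), ("b", "c", 1),
             ("w", "a", 1), ("w", "b", 1), ("w", "c", 1),
             ("u", "a", 1)]
        )
        comms = CommunitySet([{"a", "b", "c"}])
        before = attachment_probabilities(comms, net, "u").prior_pos[0]
        net.add_edge("u", "w", 1)
        after = attachment_probabilities(comms, net, "u").prior_pos[0]
        assert after >= before

    def test_table_invariants(self):
        net, comms = grid_network()
        t = attachment_probabilities(comms, net, "u")
        assert (t.total_pos >= 0).all() and (t.total_neg >= 0).all()
        assert np.allclose(t.total_pos, t.conditional_pos.T @ t.prior_pos)
        assert np.allclose(t.total_neg, t.conditional_neg.T @ t.prior_neg)
        with pytest.raises(RuntimeError):
            attachment_probabilities(comms, net, "a")
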