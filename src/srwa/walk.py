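"""Signed random walks with teleportation and attachment probabilities.

For a node ``u`` outside all current communities, this module scores how
strongly ``u`` is pulled into each community by positive links and pushed
away by negative links.  Both scores come from a damped random walk

    s_{t+1} = (1 - alpha) . M^T . s_t + alpha . d

over the nodes already inside communities, where ``M`` row-normalises a
Jaccard neighbourhood-similarity matrix (positive or negative
neighbourhoods respectively) and ``alpha`` is the teleporting
probability.  One walk is run per hypothesis "u belongs to community k"
(k = 1..q): when the walker jumps it follows the hypothesis attachment
of ``u``, so ``d`` is uniform over the k-th community's members and zero
elsewhere.  The k-th stationary vector, averaged over each community's
members, gives the conditional probability of reaching community j given
the hypothesis; the mean direct similarity of ``u`` to community k's
members gives the prior of the hypothesis; totals combine the two by the
law of total probability.

Neighbourhoods entering the similarities are the observed edges of the
network restricted to the walk nodes plus ``u``; the hypothesis edges
that formally attach ``u`` to the k-th community encode the conditioning
scenario (they set the teleport vector) and are excluded from similarity
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .network import (
    NEGATIVE,
    POSITIVE,
    CommunitySet,
    SignedNetwork,
    _label_key,
)

__all__ = [
    "WalkConfig",
    "WalkGraph",
    "ProbabilityTable",
    "ConvergenceError",
    "jaccard_similarity",
    "build_walk_graph",
    "stationary_distribution",
    "attachment_probabilities",
]


class ConvergenceError(RuntimeError):
    """Damped iteration failed to reach the requested tolerance."""


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the teleporting random walk.

    alpha : teleporting probability in (0, 1); 0.15 by default.
    tol : convergence threshold on the L1 difference of successive
        iterates.
    max_iter : iteration cap before a :class:`ConvergenceError`.
    """

    alpha: float = 0.15
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


def jaccard_similarity(
    net: SignedNetwork, vi, vj, sign: str = POSITIVE, restrict=None
) -> float:
    """Jaccard similarity of the signed neighbourhoods of two nodes.

    ``|G(vi) & G(vj)| / |G(vi) | G(vj)|`` over open neighbourhoods of the
    requested sign, optionally intersected with ``restrict`` first; 0 when
    the union is empty.
    """
    a = net.neighborhood(vi, sign)
    b = net.neighborhood(vj, sign)
    if restrict is not None:
        restrict = set(restrict)
        a &= restrict
        b &= restrict
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class WalkGraph:
    """The k-th hypothesis graph: walk nodes, u, and its edge sets.

    ``positive_edges`` holds the observed positive edges among walk nodes
    plus the hypothesis edges attaching ``u`` to every member of the k-th
    community; ``negative_edges`` holds the observed negative edges among
    walk nodes plus u's observed negative edges into the walk set.
    """

    walk_nodes: tuple
    u: object
    k: int
    positive_edges: frozenset
    negative_edges: frozenset

    @property
    def m(self) -> int:
        return len(self.walk_nodes)


def _walk_order(communities: CommunitySet) -> list:
    """Ordered union of community member sets (community order, then label)."""
    seen = set()
    order = []
    for c in communities:
        for v in sorted(c.members, key=_label_key):
            if v not in seen:
                seen.add(v)
                order.append(v)
    return order


def build_walk_graph(
    communities: CommunitySet, net: SignedNetwork, u, k: int
) -> WalkGraph:
    """Construct the hypothesis graph for "u belongs to community k"."""
    if not 0 <= k < communities.q:
        raise IndexError(f"community index {k} out of range for q={communities.q}")
    covered = communities.covered_nodes()
    if u in covered:
        raise RuntimeError(f"node {u!r} is already inside a community")
    walk_nodes = _walk_order(communities)
    walk_set = set(walk_nodes)
    pos = set()
    neg = set()
    for a, b, s in net.edges():
        if a in walk_set and b in walk_set:
            (pos if s > 0 else neg).add(frozenset((a, b)))
        elif s < 0 and {a, b} & {u} and ({a, b} - {u}) <= walk_set:
            neg.add(frozenset((a, b)))
    for v in communities[k].members:
        pos.add(frozenset((u, v)))
    return WalkGraph(
        walk_nodes=tuple(walk_nodes),
        u=u,
        k=k,
        positive_edges=frozenset(pos),
        negative_edges=frozenset(neg),
    )


def stationary_distribution(
    M, s0, d, config: WalkConfig | None = None
) -> np.ndarray:
    """Fixed point of ``s <- (1 - alpha) M^T s + alpha d`` by damped iteration.

    ``M`` must be row-stochastic (replace all-zero rows by uniform rows
    beforehand); ``s0`` and ``d`` must be probability vectors.  The damped
    map contracts the L1 distance by at least (1 - alpha) per step, so the
    fixed point is unique and independent of ``s0``.
    """
    if config is None:
        config = WalkConfig()
    M = np.asarray(M, dtype=float)
    s = np.asarray(s0, dtype=float).copy()
    d = np.asarray(d, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("M must be row-stochastic (rows summing to 1)")
    a = config.alpha
    MT = M.T.copy()
    for _ in range(config.max_iter):
        nxt = (1.0 - a) * (MT @ s) + a * d
        if np.abs(nxt - s).sum() <= config.tol:
            return nxt
        s = nxt
    resid = float(np.abs((1.0 - a) * (MT @ s) + a * d - s).sum())
    raise ConvergenceError(
        f"no convergence within {config.max_iter} iterations (L1 residual {resid:.3e})"
    )


@dataclass
class ProbabilityTable:
    """Per-community attachment probabilities of one outside node.

    ``conditional_*[k, j]`` is the mean stationary mass on community j's
    members under hypothesis k; ``prior_*[k]`` the mean direct similarity
    of u to community k's members; ``total_*[j]`` the total-probability
    combination sum_k conditional[k, j] * prior[k].
    """

    u: object
    conditional_pos: np.ndarray
    conditional_neg: np.ndarray
    prior_pos: np.ndarray
    prior_neg: np.ndarray
    total_pos: np.ndarray = field(init=False)
    total_neg: np.ndarray = field(init=False)

    def __post_init__(self):
        self.total_pos = self.conditional_pos.T @ self.prior_pos
        self.total_neg = self.conditional_neg.T @ self.prior_neg

    @property
    def q(self) -> int:
        return len(self.prior_pos)


class _WalkEngine:
    """Vectorised similarity/walk computations on a fixed network.

    Works on integer node indices and cached CSR adjacency; used by the
    public API below and by the expansion driver.
    """

    def __init__(self, net: SignedNetwork, config: WalkConfig):
        arrays = net._arrays()
        self.B = {POSITIVE: arrays["P"], NEGATIVE: arrays["N"]}
        self.config = config

    def _similarity(self, R: np.ndarray, sign: str) -> np.ndarray:
        """Dense Jaccard similarity among the restricted node set R."""
        Bw = self.B[sign][R][:, R]
        inter = np.asarray((Bw @ Bw.T).todense())
        deg = np.asarray(Bw.sum(axis=1)).ravel()
        union = deg[:, None] + deg[None, :] - inter
        return np.divide(
            inter, union, out=np.zeros_like(inter), where=union > 0
        )

    @staticmethod
    def _transition(S: np.ndarray) -> np.ndarray:
        """Row-normalise a similarity block; all-zero rows become uniform."""
        m = S.shape[0]
        rows = S.sum(axis=1)
        zero = rows == 0.0
        M = S / np.where(zero, 1.0, rows)[:, None]
        if zero.any():
            M[zero] = 1.0 / m
        return M

    def _stationary_all(self, S: np.ndarray, D: np.ndarray) -> np.ndarray:
        """Fixed points of the damped walk for every teleport column of D.

        Solves (I - (1 - alpha) M^T) pi_k = alpha d_k by one dense LU
        factorisation shared across the q hypothesis columns; this is the
        exact limit of the damped iteration, which contracts with factor
        (1 - alpha) and therefore has a unique fixed point.
        """
        a = self.config.alpha
        M = self._transition(S)
        A = np.eye(M.shape[0]) - (1.0 - a) * M.T
        return scipy.linalg.lu_solve(scipy.linalg.lu_factor(A), a * D)

    def scores(
        self, walk_idx: np.ndarray, comm_pos: list[np.ndarray], u: int
    ) -> dict:
        """Conditional, prior and total attachment scores for node u.

        walk_idx : indices of the nodes inside communities, in walk order.
        comm_pos : per community, positions of its members within walk_idx.
        Returns per sign a tuple (conditional[k, j], prior[k], total[j]).
        """
        m = len(walk_idx)
        q = len(comm_pos)
        R = np.append(walk_idx, u)
        # membership indicator: row j averages over community j's members;
        # its transpose is the per-hypothesis teleport matrix D
        ind = np.zeros((q, m))
        for j, pos in enumerate(comm_pos):
            ind[j, pos] = 1.0 / len(pos)
        out = {}
        for sign in (POSITIVE, NEGATIVE):
            S = self._similarity(R, sign)
            s0_raw = S[m, :m]
            priors = ind @ s0_raw  # mean similarity of u to each community
            if s0_raw.sum() == 0.0:
                # u has no evidence of this sign into the walk set: the
                # branch short-circuits to zero for every community
                cond = np.zeros((q, q))
            else:
                PI = self._stationary_all(S[:m, :m], ind.T)  # (m, q)
                cond = (ind @ PI).T  # cond[k, j] = mean pi_k over V_j
            out[sign] = (cond, priors, cond.T @ priors)
        return out


def attachment_probabilities(
    communities: CommunitySet,
    net: SignedNetwork,
    u,
    config: WalkConfig | None = None,
) -> ProbabilityTable:
    """Positive and negative attachment probabilities of ``u`` to each community."""
    if config is None:
        config = WalkConfig()
    if communities.q == 0:
        raise RuntimeError("no communities to attach to")
    if u in communities.covered_nodes():
        raise RuntimeError(f"node {u!r} is already inside a community")
    order = _walk_order(communities)
    pos_of = {v: i for i, v in enumerate(order)}
    walk_idx = np.array([net.index(v) for v in order], dtype=np.int64)
    comm_pos = [
        np.array(sorted(pos_of[v] for v in c.members), dtype=np.int64)
        for c in communities
    ]
    engine = _WalkEngine(net, config)
    res = engine.scores(walk_idx, comm_pos, net.index(u))
    cond_p, prior_p, _ = res[POSITIVE]
    cond_n, prior_n, _ = res[NEGATIVE]
    return ProbabilityTable(
        u=u,
        conditional_pos=cond_p,
        conditional_neg=cond_n,
        prior_pos=prior_p,
        prior_neg=prior_n,
    )
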