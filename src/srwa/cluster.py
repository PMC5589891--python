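"""Scikit-learn style estimator for signed-network community detection."""

from __future__ import annotations

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from .expansion import SrwaConfig, srwa
from .network import SignedNetwork
from .walk import WalkConfig

__all__ = ["SignedRandomWalkClustering"]


class SignedRandomWalkClustering(ClusterMixin, BaseEstimator):
    """Community detection in signed networks by seeded random walks.

    Detects initial communities around local-maximum-degree nodes and
    grows them by comparing, for every outside node, a positive
    attachment probability (random walk over positive-neighbourhood
    similarities) against a negative one (same walk over negative
    neighbourhoods); similar communities are merged and overlaps resolved
    by tightness.

    Parameters
    ----------
    alpha : float, default=0.15
        Teleporting probability of the damped walk.
    xi : float, default=0.5
        Overlap-ratio threshold above which two communities merge.
    tol : float, default=1e-10
        L1 convergence threshold of the walk iteration.
    max_iter : int, default=1000
        Iteration cap of the walk.

    Attributes
    ----------
    nodes_ : list
        Node labels in network order.
    labels_ : ndarray of shape (n_nodes,)
        Crisp community index per node, aligned with ``nodes_``.
    communities_ : list of frozenset
        Detected communities before crisping (may overlap).
    partition_ : Partition
        The crisp node -> community assignment.
    n_communities_ : int

    Examples
    --------
    >>> import numpy as np
    >>> A = np.block([[np.ones((3, 3)), -np.ones((3, 3))],
    ...               [-np.ones((3, 3)), np.ones((3, 3))]])
    >>> np.fill_diagonal(A, 0)
    >>> SignedRandomWalkClustering().fit_predict(A)
    array([0, 0, 0, 1, 1, 1])
    """

    def __init__(
        self,
        alpha: float = 0.15,
        xi: float = 0.5,
        tol: float = 1e-10,
        max_iter: int = 1000,
    ):
        self.alpha = alpha
        self.xi = xi
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _as_network(X) -> SignedNetwork:
        if isinstance(X, SignedNetwork):
            return X
        if isinstance(X, nx.Graph):
            net = SignedNetwork()
            for v in X.nodes:
                net.add_node(v)
            for u, v, data in X.edges(data=True):
                s = data.get("sign", data.get("weight", 1))
                net.add_edge(u, v, 1 if s > 0 else -1)
            return net
        if sp.issparse(X):
            return SignedNetwork.from_adjacency(X)
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError(
                "X must be a SignedNetwork, a networkx graph, or a square "
                f"signed adjacency matrix; got shape {getattr(X, 'shape', None)}"
            )
        if not np.array_equal(X, X.T):
            raise ValueError("signed adjacency matrix must be symmetric")
        if not np.isin(X, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be -1, 0 or +1")
        return SignedNetwork.from_adjacency(X)

    def fit(self, X, y=None):
        """Detect communities on a signed network.

        X : SignedNetwork, networkx.Graph with ``sign`` (or +/-1
            ``weight``) edge attributes, or a symmetric array / sparse
            matrix with entries in {-1, 0, +1}.
        """
        config = SrwaConfig(
            walk=WalkConfig(alpha=self.alpha, tol=self.tol, max_iter=self.max_iter),
            xi=self.xi,
        )
        net = self._as_network(X)
        communities, partition = srwa(net, config)
        self.nodes_ = net.nodes
        self.communities_ = communities.member_sets()
        self.partition_ = partition
        self.labels_ = partition.labels(self.nodes_)
        self.n_communities_ = int(len(set(self.labels_.tolist())))
        return self
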