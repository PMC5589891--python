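"""Signed-graph data model, degrees/neighbourhoods, and plain-text I/O.

A signed network is an undirected graph whose edges carry a sign, +1
(affinity, activation, trust) or -1 (antagonism, repression, distrust).
It is the adjacency structure a(i, j) in {-1, 0, +1} that every other
module in this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SignedNetwork",
    "Community",
    "CommunitySet",
    "Partition",
    "ParseError",
    "EdgeConflictError",
    "read_signed_edgelist",
    "write_signed_edgelist",
    "read_partition",
    "write_partition",
]

POSITIVE = "positive"
NEGATIVE = "negative"


class ParseError(ValueError):
    """Malformed line in a plain-text input file."""


class EdgeConflictError(ValueError):
    """The same node pair was given with two different signs."""


def _label_key(label):
    # total order over opaque labels: group by type name so mixed
    # int/str node sets still sort deterministically
    return (type(label).__name__, label)


def _canon(label):
    # numpy scalars hash like their Python value but break _label_key
    if isinstance(label, np.integer):
        return int(label)
    if isinstance(label, np.str_):
        return str(label)
    return label


class SignedNetwork:
    """Undirected signed graph with at most one +/-1 edge per node pair.

    Node labels are opaque hashable values kept verbatim; internal integer
    indices follow first-seen order.  Self-loops and conflicting duplicate
    edges are rejected.
    """

    def __init__(self) -> None:
        self._index: dict[Hashable, int] = {}
        self._nodes: list[Hashable] = []
        self._nbrs: list[dict[int, int]] = []  # idx -> {nbr idx: sign}
        self._cache: dict | None = None

    # -- construction ---------------------------------------------------

    def add_node(self, label: Hashable) -> int:
        label = _canon(label)
        i = self._index.get(label)
        if i is None:
            i = len(self._nodes)
            self._index[label] = i
            self._nodes.append(label)
            self._nbrs.append({})
            self._cache = None
        return i

    def add_edge(self, u: Hashable, v: Hashable, sign: int) -> None:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        i = self.add_node(u)
        j = self.add_node(v)
        if i == j:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        old = self._nbrs[i].get(j)
        if old is not None:
            if old != sign:
                raise EdgeConflictError(
                    f"conflicting signs for edge ({u!r}, {v!r}): {old} vs {sign}"
                )
            return
        self._nbrs[i][j] = sign
        self._nbrs[j][i] = sign
        self._cache = None

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable, int]],
        nodes: Iterable[Hashable] = (),
    ) -> "SignedNetwork":
        net = cls()
        for v in nodes:
            net.add_node(v)
        for u, v, s in edges:
            net.add_edge(u, v, s)
        return net

    @classmethod
    def from_adjacency(
        cls, A, nodes: Sequence[Hashable] | None = None
    ) -> "SignedNetwork":
        """Build from a symmetric matrix with entries in {-1, 0, +1}."""
        A = sp.coo_matrix(A)
        n = A.shape[0]
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if nodes is None:
            nodes = range(n)
        nodes = list(nodes)
        if len(nodes) != n:
            raise ValueError("node labels do not match matrix size")
        net = cls()
        for v in nodes:
            net.add_node(v)
        for i, j, w in zip(A.row, A.col, A.data):
            if w == 0 or i > j:
                continue
            net.add_edge(nodes[i], nodes[j], int(w))
        return net

    # -- basic queries ---------------------------------------------------

    @property
    def nodes(self) -> list[Hashable]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self._nbrs) // 2

    def __contains__(self, label: Hashable) -> bool:
        return _canon(label) in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def index(self, label: Hashable) -> int:
        try:
            return self._index[_canon(label)]
        except KeyError:
            raise KeyError(f"unknown node {label!r}") from None

    def label(self, i: int) -> Hashable:
        return self._nodes[i]

    def edges(self) -> Iterator[tuple[Hashable, Hashable, int]]:
        for i, d in enumerate(self._nbrs):
            for j, s in d.items():
                if i < j:
                    yield self._nodes[i], self._nodes[j], s

    def sign(self, u: Hashable, v: Hashable) -> int:
        """Adjacency entry a(u, v): +1, -1 or 0 when no edge exists."""
        return self._nbrs[self.index(u)].get(self.index(v), 0)

    def degree(self, v: Hashable) -> tuple[int, int, int]:
        """(total, positive, negative) degree; negative as a magnitude.

        The node degree is the positive degree plus the magnitude of the
        negative degree: deg(v) = deg_P(v) + |deg_N(v)|.
        """
        d = self._nbrs[self.index(v)]
        pos = sum(1 for s in d.values() if s > 0)
        neg = len(d) - pos
        return pos + neg, pos, neg

    def neighborhood(self, v: Hashable, sign: str = POSITIVE) -> set:
        """Open neighbourhood of ``v`` through edges of one sign."""
        want = 1 if sign == POSITIVE else -1
        d = self._nbrs[self.index(v)]
        return {self._nodes[j] for j, s in d.items() if s == want}

    # -- array views -----------------------------------------------------

    def _arrays(self) -> dict:
        """Cached CSR boolean adjacency per sign plus degree vectors."""
        if self._cache is None:
            n = len(self._nodes)
            ri, ci, si = [], [], []
            for i, d in enumerate(self._nbrs):
                for j, s in d.items():
                    ri.append(i)
                    ci.append(j)
                    si.append(s)
            signs = np.asarray(si, dtype=np.int8)
            rows = np.asarray(ri, dtype=np.int64)
            cols = np.asarray(ci, dtype=np.int64)
            P = sp.csr_matrix(
                ((signs > 0).astype(np.float64), (rows, cols)), shape=(n, n)
            )
            N = sp.csr_matrix(
                ((signs < 0).astype(np.float64), (rows, cols)), shape=(n, n)
            )
            P.eliminate_zeros()
            N.eliminate_zeros()
            self._cache = {
                "P": P,
                "N": N,
                "deg_pos": np.asarray(P.sum(axis=1)).ravel().astype(np.int64),
                "deg_neg": np.asarray(N.sum(axis=1)).ravel().astype(np.int64),
            }
        return self._cache

    def signed_adjacency(self) -> sp.csr_matrix:
        """n x n CSR matrix with entries in {-1, 0, +1}."""
        a = self._arrays()
        return (a["P"] - a["N"]).tocsr()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for u, v, s in self.edges():
            g.add_edge(u, v, sign=s, weight=s)
        return g


@dataclass(frozen=True)
class Community:
    """A node group; induced signed link sets are derived on demand."""

    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError("a community must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, v) -> bool:
        return v in self.members

    def induced_edges(self, net: SignedNetwork, sign: str = POSITIVE):
        want = 1 if sign == POSITIVE else -1
        return {
            frozenset((u, v))
            for u, v, s in net.edges()
            if s == want and u in self.members and v in self.members
        }


class CommunitySet:
    """Ordered collection of communities; overlap is permitted."""

    def __init__(self, communities: Iterable) -> None:
        self.communities: list[Community] = [
            c if isinstance(c, Community) else Community(frozenset(c))
            for c in communities
        ]

    @property
    def q(self) -> int:
        return len(self.communities)

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self):
        return iter(self.communities)

    def __getitem__(self, k: int) -> Community:
        return self.communities[k]

    def member_sets(self) -> list[frozenset]:
        return [c.members for c in self.communities]

    def covered_nodes(self) -> set:
        out: set = set()
        for c in self.communities:
            out |= c.members
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunitySet):
            return NotImplemented
        return self.member_sets() == other.member_sets()

    def __repr__(self) -> str:
        return f"CommunitySet(q={self.q})"


@dataclass
class Partition:
    """Crisp node -> community-index assignment."""

    assignment: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, nodes: Sequence, labels: Sequence[int]) -> "Partition":
        if len(nodes) != len(labels):
            raise ValueError("nodes and labels differ in length")
        return cls({_canon(v): int(c) for v, c in zip(nodes, labels)})

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable]) -> "Partition":
        out: dict = {}
        for k, c in enumerate(communities):
            for v in c:
                out[_canon(v)] = k
        return cls(out)

    def labels(self, nodes: Sequence) -> np.ndarray:
        return np.asarray([self.assignment[_canon(v)] for v in nodes])

    def communities(self) -> list[set]:
        groups: dict[int, set] = {}
        for v, c in self.assignment.items():
            groups.setdefault(c, set()).add(v)
        return [groups[c] for c in sorted(groups)]

    def __len__(self) -> int:
        return len(self.assignment)

    def __getitem__(self, v):
        return self.assignment[_canon(v)]


# -- file formats --------------------------------------------------------


def read_signed_edgelist(path, comments: str = "#") -> SignedNetwork:
    """Read a whitespace-separated ``u v sign`` edge list.

    Lines starting with ``comments`` and blank lines are ignored; node
    labels are kept verbatim as strings.  Raises :class:`ParseError` with
    the offending line number on malformed input and
    :class:`EdgeConflictError` on duplicate pairs with conflicting signs.
    """
    net = SignedNetwork()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comments):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'node node sign', got {line!r}"
                )
            u, v, raw = parts[0], parts[1], parts[2]
            try:
                s = int(raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: sign {raw!r} is not an integer"
                ) from None
            if s not in (1, -1):
                raise ParseError(f"{path}:{lineno}: sign must be 1 or -1, got {s}")
            if u == v:
                raise ParseError(f"{path}:{lineno}: self-loop on node {u!r}")
            net.add_edge(u, v, s)
    return net


def write_signed_edgelist(net: SignedNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, s in net.edges():
            fh.write(f"{u}\t{v}\t{s}\n")


def write_partition(partition: Partition, path) -> None:
    """Write tab-separated ``node<TAB>community_id`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for v, c in partition.assignment.items():
            fh.write(f"{v}\t{c}\n")


def read_partition(path) -> Partition:
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'node<TAB>community', got {line!r}"
                )
            try:
                out[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: community id {parts[1]!r} is not an integer"
                ) from None
    return Partition(out)
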