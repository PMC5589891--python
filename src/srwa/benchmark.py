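"""Signed LFR benchmark generator.

Generates planted-partition test networks in two stages, mirroring the
usual LFR construction extended to edge signs:

1. An unsigned graph with a truncated power-law degree sequence
   (exponent ``t1``, mean ``k``, maximum ``maxk``) and power-law
   community sizes (exponent ``t2`` within ``[minc, maxc]``); each node
   places a fraction ``1 - mu`` of its links inside its planted
   community and ``mu`` outside.
2. Sign assignment: within-community links are positive and
   between-community links negative, after which a fraction ``p_minus``
   of the within-community links is flipped negative and a fraction
   ``p_plus`` of the between-community links flipped positive
   (``round(fraction * pool)`` uniformly chosen edges).

The statistical contract, not the wiring algorithm, is normative: the
realised mean degree tracks ``k``, community sizes stay within bounds,
the per-node external-link fraction tracks ``mu``, and flip counts are
exact.  Internal wiring uses Havel-Hakimi realisation randomised by
degree-preserving double edge swaps; external wiring uses stub matching
with swap repair; a node whose target internal degree exceeds its
community's size minus one is capped (the excess becomes external), as
in the classic benchmark's dense regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .network import Partition, SignedNetwork

__all__ = [
    "LfrParams",
    "GroundTruth",
    "GenerationError",
    "generate_unsigned_lfr",
    "apply_signs",
    "generate_signed_lfr",
]


class GenerationError(RuntimeError):
    """Benchmark generation failed under the requested parameters."""


@dataclass(frozen=True)
class LfrParams:
    """Parameters of the signed LFR generator SRN(n, k, maxk, t1, t2, minc,
    maxc, on, om, mu, p_minus, p_plus).

    Defaults are the 128-node study conditions: n=128, k=16, maxk=50,
    t1=2, t2=1, minc=10, maxc=30, non-overlapping ground truth.
    """

    n: int = 128
    k: float = 16.0
    maxk: int = 50
    t1: float = 2.0
    t2: float = 1.0
    minc: int = 10
    maxc: int = 30
    on: int = 0
    om: int = 0
    mu: float = 0.1
    p_minus: float = 0.0
    p_plus: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if not 0 <= self.p_minus <= 1 or not 0 <= self.p_plus <= 1:
            raise ValueError("p_minus and p_plus must lie in [0, 1]")
        if not self.minc <= self.maxc <= self.n:
            raise ValueError("need minc <= maxc <= n")
        if not 1 <= self.k <= self.maxk:
            raise ValueError("need 1 <= k <= maxk")


@dataclass(frozen=True)
class GroundTruth:
    """Planted node -> community-label assignment."""

    planted: dict

    def to_partition(self) -> Partition:
        return Partition(dict(self.planted))

    def communities(self) -> list[set]:
        return self.to_partition().communities()

    def __len__(self) -> int:
        return len(self.planted)


# -- truncated power-law sampling ----------------------------------------


def _plaw_mean(xmin: float, xmax: float, gamma: float) -> float:
    """Mean of the continuous power law x^-gamma truncated to [xmin, xmax]."""
    if abs(gamma - 1.0) < 1e-12:
        norm = np.log(xmax / xmin)
        return (xmax - xmin) / norm
    norm = (xmax ** (1.0 - gamma) - xmin ** (1.0 - gamma)) / (1.0 - gamma)
    if abs(gamma - 2.0) < 1e-12:
        top = np.log(xmax / xmin)
    else:
        top = (xmax ** (2.0 - gamma) - xmin ** (2.0 - gamma)) / (2.0 - gamma)
    return top / norm


def _plaw_sample(
    rng: np.random.Generator, size: int, xmin: float, xmax: float, gamma: float
) -> np.ndarray:
    """Inverse-CDF samples of the truncated continuous power law."""
    u = rng.random(size)
    if abs(gamma - 1.0) < 1e-12:
        return xmin * (xmax / xmin) ** u
    a = 1.0 - gamma
    return (xmin**a + u * (xmax**a - xmin**a)) ** (1.0 / a)


def _degree_sequence(rng, params: LfrParams, max_size: int) -> np.ndarray:
    """Integer degrees with mean ~= k, max <= maxk, power-law exponent t1.

    The draw is truncated so that a node's internal degree
    (1 - mu) * d fits inside the largest realised community
    (``max_size``); without this a dense node cannot place its planted
    share of internal links and the excess would spill into spurious
    between-community links, inflating the realised mixing beyond mu.
    The lower truncation point is then re-solved so the mean stays at k.
    """
    xmax = float(params.maxk)
    if params.mu < 1.0:
        xmax = min(xmax, (max_size - 1) / (1.0 - params.mu))
    xmax = max(xmax, params.k)
    lo, hi = 1.0, xmax - 1e-9
    if _plaw_mean(lo, xmax, params.t1) > params.k:
        hi = lo  # degenerate: even xmin=1 overshoots; clip handles it
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _plaw_mean(mid, xmax, params.t1) < params.k:
            lo = mid
        else:
            hi = mid
    xmin = 0.5 * (lo + hi)
    deg = np.rint(_plaw_sample(rng, params.n, xmin, xmax, params.t1)).astype(
        np.int64
    )
    deg = np.clip(deg, 1, params.maxk)
    if deg.sum() % 2:
        deg[int(np.argmax(deg))] -= 1
    return deg


def _community_sizes(rng, params: LfrParams) -> list[int]:
    """Power-law community sizes in [minc, maxc] summing exactly to n."""
    n, minc, maxc = params.n, params.minc, params.maxc
    for _ in range(200):
        sizes: list[int] = []
        while sum(sizes) < n:
            s = int(
                np.rint(_plaw_sample(rng, 1, float(minc), float(maxc), params.t2))[0]
            )
            sizes.append(int(np.clip(s, minc, maxc)))
        excess = sum(sizes) - n
        # shave the excess off the smallest communities still above minc,
        # preserving the large sizes that dense nodes need
        guard = 10 * n
        while excess > 0 and guard > 0:
            guard -= 1
            above = [j for j, s in enumerate(sizes) if s > minc]
            if not above:
                break
            j = min(above, key=lambda j: sizes[j])
            sizes[j] -= 1
            excess -= 1
        if excess > 0 and len(sizes) > 1:
            # all at minc: drop one community and grow the others
            sizes.pop()
            deficit = n - sum(sizes)
            guard = 10 * n
            while deficit > 0 and guard > 0:
                guard -= 1
                j = int(np.argmin(sizes))
                if sizes[j] < maxc:
                    sizes[j] += 1
                    deficit -= 1
                else:
                    break
            if deficit != 0:
                continue
            excess = 0
        if excess == 0 and sum(sizes) == n and all(minc <= s <= maxc for s in sizes):
            return sizes
    raise GenerationError(
        f"could not partition n={n} into community sizes within [{minc}, {maxc}]"
    )


def _assign_nodes(
    rng, sizes: list[int], internal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Place nodes into fixed-size communities, capping internal degrees.

    Returns (community label per node, possibly capped internal degrees).
    Nodes are placed in decreasing internal-degree order into the
    fitting community with the most free slots; when no community can
    host the full internal degree, the internal degree is capped at the
    chosen community's size minus one.
    """
    n = len(internal)
    order = rng.permutation(n)
    order = order[np.argsort(-internal[order], kind="stable")]
    free = np.asarray(sizes, dtype=np.int64).copy()
    sizes_arr = np.asarray(sizes, dtype=np.int64)
    comm = np.full(n, -1, dtype=np.int64)
    capped = internal.copy()
    for v in order:
        fits = np.flatnonzero((free > 0) & (sizes_arr - 1 >= internal[v]))
        if fits.size:
            # uniform among fitting communities, weighted by free slots,
            # so dense nodes spread over all communities able to host them
            best = int(rng.choice(fits, p=free[fits] / free[fits].sum()))
        else:
            open_ = np.flatnonzero(free > 0)
            big = open_[sizes_arr[open_] == sizes_arr[open_].max()]
            best = int(rng.choice(big))
        c = best
        comm[v] = c
        free[c] -= 1
        capped[v] = min(capped[v], sizes_arr[c] - 1)
    return comm, capped


def _wire_internal(rng, members: np.ndarray, idegs: np.ndarray) -> set:
    """Random graph on ``members`` with (approximately) the given degrees."""
    seq = idegs.copy()
    if seq.sum() % 2:
        j = int(np.argmax(seq))
        seq[j] -= 1
    while seq.sum() > 0 and not nx.is_graphical(seq.tolist()):
        top = np.argsort(-seq)[:2]
        seq[top] = np.maximum(seq[top] - 1, 0)
    if seq.sum() == 0:
        return set()
    g = nx.havel_hakimi_graph(seq.tolist())
    if g.number_of_edges() >= 2:
        try:
            nx.double_edge_swap(
                g,
                nswap=4 * g.number_of_edges(),
                max_tries=100 * g.number_of_edges(),
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXException:
            pass  # partial randomisation is fine; degrees are intact
    return {frozenset((int(members[a]), int(members[b]))) for a, b in g.edges()}


def _wire_external(
    rng, ext: np.ndarray, comm: np.ndarray
) -> set:
    """Cross-community stub matching with degree-preserving swap repair."""
    stubs = np.repeat(np.arange(len(ext)), ext)
    rng.shuffle(stubs)
    if len(stubs) % 2:
        stubs = stubs[:-1]
    edges: set = set()
    edge_list: list[tuple[int, int]] = []

    def ok(a: int, b: int) -> bool:
        return a != b and comm[a] != comm[b] and frozenset((a, b)) not in edges

    bad = []
    for a, b in zip(stubs[0::2], stubs[1::2]):
        a, b = int(a), int(b)
        if ok(a, b):
            edges.add(frozenset((a, b)))
            edge_list.append((a, b))
        else:
            bad.append((a, b))
    for a, b in bad:
        placed = False
        for _ in range(200):
            if not edge_list:
                break
            i = int(rng.integers(len(edge_list)))
            c, d = edge_list[i]
            for x, y in ((c, d), (d, c)):
                if ok(a, x) and ok(b, y) and frozenset((a, x)) != frozenset((b, y)):
                    edges.discard(frozenset((c, d)))
                    edge_list[i] = edge_list[-1]
                    edge_list.pop()
                    edges.add(frozenset((a, x)))
                    edges.add(frozenset((b, y)))
                    edge_list.append((a, x))
                    edge_list.append((b, y))
                    placed = True
                    break
            if placed:
                break
        # unplaceable stubs are dropped
    return edges


def generate_unsigned_lfr(params: LfrParams) -> tuple[SignedNetwork, GroundTruth]:
    """Planted-partition LFR graph with all-positive edges."""
    if params.on or params.om:
        raise GenerationError("overlapping ground truth (on/om > 0) is not supported")
    rng = np.random.default_rng(params.seed)
    last_err: Exception | None = None
    for _ in range(10):
        try:
            sizes = _community_sizes(rng, params)
            deg = _degree_sequence(rng, params, max(sizes))
            internal = np.rint((1.0 - params.mu) * deg).astype(np.int64)
            internal = np.minimum(internal, deg)
            comm, internal = _assign_nodes(rng, sizes, internal)
            all_edges: set = set()
            for c in range(len(sizes)):
                members = np.flatnonzero(comm == c)
                all_edges |= _wire_internal(rng, members, internal[members])
            achieved_int = np.zeros(params.n, dtype=np.int64)
            for e in all_edges:
                for v in e:
                    achieved_int[v] += 1
            if params.mu > 0:
                ext = np.maximum(deg - achieved_int, 0)
                all_edges |= _wire_external(rng, ext, comm)
            net = SignedNetwork()
            for v in range(params.n):
                net.add_node(v)
            for e in all_edges:
                a, b = sorted(e)
                net.add_edge(a, b, 1)
            truth = GroundTruth({v: int(comm[v]) for v in range(params.n)})
            return net, truth
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"generation failed after retries under {params}: {last_err}"
    )


def apply_signs(
    net: SignedNetwork,
    truth: GroundTruth,
    p_minus: float,
    p_plus: float,
    seed=None,
) -> SignedNetwork:
    """Sign the edges of a planted-partition graph.

    Within-community edges become positive and between-community edges
    negative; then ``round(p_minus * n_intra)`` intra edges are flipped
    negative and ``round(p_plus * n_inter)`` inter edges flipped
    positive, chosen uniformly.  Topology is preserved exactly.
    """
    if not 0 <= p_minus <= 1 or not 0 <= p_plus <= 1:
        raise ValueError("p_minus and p_plus must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = truth.planted
    intra, inter = [], []
    for u, v, _ in net.edges():
        (intra if labels[u] == labels[v] else inter).append((u, v))
    signs: dict = {}
    for pool, base, frac in ((intra, 1, p_minus), (inter, -1, p_plus)):
        for e in pool:
            signs[e] = base
        n_flip = int(round(frac * len(pool)))
        if n_flip:
            for i in rng.choice(len(pool), size=n_flip, replace=False):
                signs[pool[i]] = -base
    out = SignedNetwork()
    for v in net.nodes:
        out.add_node(v)
    for (u, v), s in signs.items():
        out.add_edge(u, v, s)
    return out


def generate_signed_lfr(params: LfrParams) -> tuple[SignedNetwork, GroundTruth]:
    """Full signed benchmark: unsigned LFR graph plus sign assignment."""
    rng = np.random.default_rng(params.seed)
    unsigned, truth = generate_unsigned_lfr(
        replace(params, seed=int(rng.integers(2**31 - 1)))
    )
    signed = apply_signs(
        unsigned,
        truth,
        params.p_minus,
        params.p_plus,
        seed=np.random.default_rng(int(rng.integers(2**31 - 1))),
    )
    return signed, truth
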