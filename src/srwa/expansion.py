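"""Community expansion driver: grow, spawn, merge, crisp.

The driver seeds initial triad communities, then processes the remaining
nodes in ascending total degree (low-degree nodes carry the fewest noisy
cross-community links, so handling them first spawns clean seed
communities before the well-connected nodes are attached).  Each node u
is attached to the community with the largest positive attachment
probability among those where the positive probability strictly exceeds
the negative one; failing that, a new triad community around u is
spawned (it may overlap communities that already hold u's close
neighbours, and the final merge pass then folds it back); failing that,
u goes to the community of maximum tightness (the fraction of members
positively linked to u), or becomes a singleton when every tightness is
zero.
Overlapping communities whose overlap ratio |Ci & Cj| / min(|Ci|, |Cj|)
strictly exceeds the threshold xi are merged greedily, largest ratio
first, and a crisp partition is derived by maximum tightness.

All tie-breaks are total orders, so the driver is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    NEGATIVE,
    POSITIVE,
    Community,
    CommunitySet,
    Partition,
    SignedNetwork,
    _label_key,
)
from .seeding import build_initial_community, initial_communities
from .walk import WalkConfig, _WalkEngine

__all__ = ["SrwaConfig", "tightness", "merge_pass", "srwa"]


@dataclass(frozen=True)
class SrwaConfig:
    """Driver parameters: walk settings plus the merge threshold xi."""

    walk: WalkConfig = field(default_factory=WalkConfig)
    xi: float = 0.5

    def __post_init__(self):
        if not 0 < self.xi <= 1:
            raise ValueError(f"xi must lie in (0, 1], got {self.xi}")


def tightness(net: SignedNetwork, u, community) -> float:
    """Fraction of community members positively linked to ``u``."""
    members = community.members if isinstance(community, Community) else set(community)
    if not members:
        raise ValueError("tightness of an empty community is undefined")
    iu = net.index(u)
    nbrs = net._nbrs[iu]
    hits = sum(1 for v in members if nbrs.get(net.index(v), 0) > 0)
    return hits / len(members)


def _merge_sets(sets: list[set], xi: float) -> list[set]:
    """Greedy largest-overlap-ratio merging; ties go to the lowest pair."""
    sets = [set(s) for s in sets]
    while True:
        best = None
        best_ratio = xi
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = len(sets[i] & sets[j])
                if inter == 0:
                    continue
                ratio = inter / min(len(sets[i]), len(sets[j]))
                if ratio > best_ratio:
                    best_ratio = ratio
                    best = (i, j)
        if best is None:
            return sets
        i, j = best
        sets[i] |= sets[j]
        del sets[j]


def merge_pass(communities: CommunitySet, xi: float = 0.5) -> CommunitySet:
    """Merge community pairs whose overlap ratio strictly exceeds ``xi``."""
    if not 0 < xi <= 1:
        raise ValueError(f"xi must lie in (0, 1], got {xi}")
    return CommunitySet(_merge_sets(communities.member_sets(), xi))


def srwa(
    net: SignedNetwork, config: SrwaConfig | None = None
) -> tuple[CommunitySet, Partition]:
    """Detect communities in a signed network.

    Returns the (possibly overlapping) merged community set and the crisp
    partition derived from it by maximum tightness.
    """
    if config is None:
        config = SrwaConfig()
    if net.n_nodes == 0:
        raise ValueError("cannot detect communities in an empty network")

    labels = net.nodes
    init = initial_communities(net)
    comms: list[set[int]] = [
        {net.index(v) for v in c.members} for c in init
    ]

    # walk-order bookkeeping: position of each covered node in the walk
    # vector; nodes keep their position as communities grow
    order: list[int] = []
    pos_of: dict[int, int] = {}
    comm_pos: list[list[int]] = []

    def place(i: int) -> int:
        p = pos_of.get(i)
        if p is None:
            p = len(order)
            pos_of[i] = p
            order.append(i)
        return p

    for c in comms:
        comm_pos.append([place(i) for i in sorted(c, key=lambda i: _label_key(labels[i]))])

    assigned: set[int] = set().union(*comms)
    todo = [net.index(v) for v in labels if net.index(v) not in assigned]
    todo.sort(key=lambda i: (net.degree(labels[i])[0], _label_key(labels[i])))

    engine = _WalkEngine(net, config.walk)
    pos_adj = net._arrays()["P"]

    def tightness_idx(u: int, members: set[int]) -> float:
        row = pos_adj.indices[pos_adj.indptr[u] : pos_adj.indptr[u + 1]]
        return len(members.intersection(row)) / len(members)

    for u in todo:
        if u in assigned:
            continue
        walk_idx = np.asarray(order, dtype=np.int64)
        cpos = [np.asarray(p, dtype=np.int64) for p in comm_pos]
        res = engine.scores(walk_idx, cpos, u)
        total_pos = res[POSITIVE][2]
        total_neg = res[NEGATIVE][2]
        temp = np.flatnonzero(total_pos > total_neg)
        if temp.size:
            best = int(temp[int(np.argmax(total_pos[temp]))])
            comms[best].add(u)
            comm_pos[best].append(place(u))
            assigned.add(u)
            continue
        cand = build_initial_community(net, labels[u])
        cand_idx = {net.index(v) for v in cand.members}
        if len(cand_idx) >= 2:
            comms.append(cand_idx)
            comm_pos.append(
                [place(i) for i in sorted(cand_idx, key=lambda i: _label_key(labels[i]))]
            )
            assigned |= cand_idx
            continue
        # tightness fallback; ties -> larger community, then lowest index
        best_j, best_key = None, (0.0, 0)
        for j, members in enumerate(comms):
            t = tightness_idx(u, members)
            if t <= 0.0:
                continue
            key = (t, len(members))
            if key > best_key:
                best_key, best_j = key, j
        if best_j is None:
            comms.append({u})
            comm_pos.append([place(u)])
        else:
            comms[best_j].add(u)
            comm_pos[best_j].append(place(u))
        assigned.add(u)

    merged = _merge_sets(comms, config.xi)

    # crisp overlapping memberships by maximum tightness
    crisp: dict = {}
    for i, v in enumerate(labels):
        holders = [j for j, c in enumerate(merged) if i in c]
        if len(holders) == 1:
            crisp[v] = holders[0]
        else:
            best_j, best_key = holders[0], (-1.0, 0)
            for j in holders:
                key = (tightness_idx(i, merged[j]), len(merged[j]))
                if key > best_key:
                    best_key, best_j = key, j
            crisp[v] = best_j

    community_set = CommunitySet(
        [frozenset(labels[i] for i in c) for c in merged]
    )
    # renumber crisp labels densely in community order
    used = sorted(set(crisp.values()))
    remap = {j: r for r, j in enumerate(used)}
    partition = Partition({v: remap[j] for v, j in crisp.items()})
    return community_set, partition
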