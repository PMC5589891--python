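"""Seed detection and initial triad communities.

A *local maximum degree node* has a total signed degree (positive degree
plus the magnitude of the negative degree) strictly larger than every one
of its neighbours, through edges of either sign.  Around each such seed a
small dense nucleus is built: the seed, its neighbour of largest positive
degree, and (when one exists) their common neighbour of largest positive
degree.  These triads are the communities the expansion stage grows.
"""

from __future__ import annotations

from .network import Community, CommunitySet, SignedNetwork, _label_key

__all__ = [
    "local_max_degree_nodes",
    "build_initial_community",
    "initial_communities",
]


def local_max_degree_nodes(net: SignedNetwork) -> set:
    """All nodes whose degree strictly exceeds that of every neighbour.

    Any connected component with no strict local maximum (e.g. a regular
    component) falls back to its maximum-degree node, ties broken by
    lowest label, so every component contributes at least one seed.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot seed an empty network")
    deg = {v: net.degree(v)[0] for v in net.nodes}
    seeds = set()
    for v in net.nodes:
        nbrs = net._nbrs[net.index(v)]
        if all(deg[v] > deg[net.label(j)] for j in nbrs):
            seeds.add(v)
    # per-component fallback for components the strict rule left empty
    seen: set = set()
    for start in net.nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for j in net._nbrs[net.index(x)]:
                w = net.label(j)
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        if not comp & seeds:
            top = max(deg[v] for v in comp)
            seeds.add(min((v for v in comp if deg[v] == top), key=_label_key))
    return seeds


def _largest_positive_degree(net: SignedNetwork, candidates) -> object:
    """Candidate with the largest positive degree; ties -> lowest label."""
    return min(
        candidates,
        key=lambda v: (-net.degree(v)[1], _label_key(v)),
    )


def build_initial_community(net: SignedNetwork, seed) -> Community:
    """Triad nucleus around ``seed``: seed, best neighbour, best common neighbour.

    The members of an initial community must be linked closely by
    positive links, so the second member is the *positive* neighbour of
    the seed with the largest positive degree, and the third the common
    positive neighbour of the pair with the largest positive degree (if
    any); ties break to the lowest label.  A seed without positive
    neighbours yields the singleton community.
    """
    net.index(seed)  # raise KeyError early on unknown nodes
    nbrs = net.neighborhood(seed, "positive")
    if not nbrs:
        return Community(frozenset([seed]))
    # the triad is meant to be a dense nucleus of close neighbours, so
    # prefer a second member that already shares a positive neighbour
    # with the seed (triangle support); otherwise any positive neighbour
    close = {
        v
        for v in nbrs
        if (nbrs & net.neighborhood(v, "positive")) - {seed, v}
    }
    node2 = _largest_positive_degree(net, close or nbrs)
    common = nbrs & net.neighborhood(node2, "positive")
    common.discard(seed)
    common.discard(node2)
    members = {seed, node2}
    if common:
        members.add(_largest_positive_degree(net, common))
    return Community(frozenset(members))


def initial_communities(net: SignedNetwork) -> CommunitySet:
    """One triad per local-maximum-degree seed, deduplicated and ordered.

    Communities with identical member sets are collapsed; the result is
    ordered by lowest member label.
    """
    seeds = local_max_degree_nodes(net)
    seen = set()
    out = []
    for s in seeds:
        c = build_initial_community(net, s)
        if c.members not in seen:
            seen.add(c.members)
            out.append(c)
    out.sort(key=lambda c: _label_key(min(c.members, key=_label_key)))
    return CommunitySet(out)
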