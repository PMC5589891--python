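"""Shared fixtures and brute-force helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from srwa import SignedNetwork


def set_partitions(items):
    """All set partitions of a sequence (exhaustive enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def random_signed_network(rng, n=8, p_edge=0.5, p_neg=0.3) -> SignedNetwork:
    net = SignedNetwork()
    for v in range(n):
        net.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                net.add_edge(i, j, -1 if rng.random() < p_neg else 1)
    return net


def clique_partition_network(blocks) -> SignedNetwork:
    """Complete signed graph: positive cliques on blocks, negative between."""
    net = SignedNetwork()
    label = {}
    for b, block in enumerate(blocks):
        for v in block:
            net.add_node(v)
            label[v] = b
    nodes = net.nodes
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            net.add_edge(u, v, 1 if label[u] == label[v] else -1)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def two_cliques():
    """Two positive 4-cliques joined by two negative edges."""
    net = SignedNetwork()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                net.add_edge(base + i, base + j, 1)
    net.add_edge(0, 4, -1)
    net.add_edge(1, 5, -1)
    return net
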