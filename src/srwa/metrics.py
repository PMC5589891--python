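"""Quality measures for signed-network partitions.

Normalised mutual information compares a detected partition against a
reference one through the confusion matrix X (X_ij = nodes shared by
reference community i and found community j):

    NMI = -2 sum_ij X_ij log(X_ij N / (X_i. X_.j))
          / [sum_i X_i. log(X_i./N) + sum_j X_.j log(X_.j/N)]

with 0 log 0 := 0; it is 1 exactly for relabel-identical partitions.

Signed modularity extends Newman modularity with separate null models for
positive and negative link strengths:

    Q_signed = 1/(2w+ + 2w-) sum_ij [w_ij - (w_i+ w_j+ / 2w+
                                             - w_i- w_j- / 2w-)] delta(c_i, c_j)

where w_ij is the signed adjacency entry, w_i+/w_i- are per-node positive
and negative strengths (magnitudes), and w+/w- the total strengths.  A
null-model term whose denominator is zero contributes nothing.
"""

from __future__ import annotations

import numpy as np

from .network import Partition, SignedNetwork

__all__ = ["confusion_matrix", "nmi", "signed_modularity"]


def confusion_matrix(real: Partition, found: Partition) -> np.ndarray:
    """Counts X_ij of nodes in reference community i and found community j."""
    nodes = set(real.assignment)
    if nodes != set(found.assignment):
        raise ValueError("partitions cover different node sets")
    ri = {c: i for i, c in enumerate(sorted(set(real.assignment.values())))}
    fj = {c: j for j, c in enumerate(sorted(set(found.assignment.values())))}
    X = np.zeros((len(ri), len(fj)), dtype=np.int64)
    for v in nodes:
        X[ri[real.assignment[v]], fj[found.assignment[v]]] += 1
    return X


def nmi(real: Partition, found: Partition) -> float:
    """Normalised mutual information between two crisp partitions of one node set."""
    X = confusion_matrix(real, found).astype(float)
    N = X.sum()
    if N == 0:
        raise ValueError("partitions are empty")
    row = X.sum(axis=1)
    col = X.sum(axis=0)
    nz = X > 0
    num = -2.0 * np.sum(X[nz] * np.log(X[nz] * N / np.outer(row, col)[nz]))
    den = np.sum(row * np.log(row / N)) + np.sum(col * np.log(col / N))
    if den == 0.0:
        # both partitions trivial (single community each): identical
        return 1.0
    return float(num / den)


def signed_modularity(net: SignedNetwork, partition: Partition) -> float:
    """Signed modularity of a crisp partition."""
    nodes = net.nodes
    if set(partition.assignment) != set(nodes):
        raise ValueError("partition does not cover exactly the network's nodes")
    arrays = net._arrays()
    P, N = arrays["P"], arrays["N"]
    wi_pos = arrays["deg_pos"].astype(float)
    wi_neg = arrays["deg_neg"].astype(float)
    w_pos = wi_pos.sum() / 2.0
    w_neg = wi_neg.sum() / 2.0
    if w_pos + w_neg == 0:
        return 0.0
    labels = partition.labels(nodes)
    total = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        A_sub = (P[idx][:, idx] - N[idx][:, idx]).sum()
        total += A_sub
        if w_pos > 0:
            total -= wi_pos[idx].sum() ** 2 / (2.0 * w_pos)
        if w_neg > 0:
            total += wi_neg[idx].sum() ** 2 / (2.0 * w_neg)
    return float(total / (2.0 * w_pos + 2.0 * w_neg))
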