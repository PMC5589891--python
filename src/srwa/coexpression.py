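"""Signed gene co-expression network construction.

Two genes are linked when the sample Pearson correlation of their
expression profiles passes a hard threshold: a positive edge for
r > threshold, a negative edge for r < -threshold, no edge otherwise
(strict inequalities).  The default threshold is 0.8.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import ParseError, SignedNetwork

__all__ = ["read_expression_matrix", "correlation_network"]


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV: first column gene labels, header row samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 3:
        raise ValueError(
            f"need at least 3 samples for a defined correlation, got {df.shape[1]}"
        )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value in {path}: {exc}") from None
    if df.isna().any().any():
        raise ParseError(f"missing expression values in {path}")
    return df


def correlation_network(expr: pd.DataFrame, threshold: float = 0.8) -> SignedNetwork:
    """Build the signed co-expression network of an expression matrix.

    Parameters
    ----------
    expr : DataFrame, shape (n_genes, n_samples)
        Real-valued expression table, gene labels on the index.
    threshold : float in (0, 1)
        Correlation cut-off; edges require ``|r|`` strictly above it.

    Zero-variance genes have undefined correlations and produce no edges.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if expr.shape[1] < 3:
        raise ValueError(
            f"need at least 3 samples for a defined correlation, got {expr.shape[1]}"
        )
    X = np.asarray(expr, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression matrix contains NaN or infinite values")
    genes = list(expr.index)

    net = SignedNetwork()
    for g in genes:
        net.add_node(g)

    sd = X.std(axis=1)
    ok = sd > 0
    if ok.sum() >= 2:
        idx = np.flatnonzero(ok)
        R = np.corrcoef(X[idx])
        iu, ju = np.triu_indices(len(idx), k=1)
        r = R[iu, ju]
        for a, b, rv in zip(iu, ju, r):
            if rv > threshold:
                net.add_edge(genes[idx[a]], genes[idx[b]], 1)
            elif rv < -threshold:
                net.add_edge(genes[idx[a]], genes[idx[b]], -1)
    return net
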