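"""Co-expression and differential network construction.

Networks are ``networkx.Graph`` objects whose nodes are gene identifiers
and whose edges carry the Pearson correlation of the two genes' time series
as ``weight``. A co-expression network keeps the gene pairs whose
correlation reaches the chosen upper quantile of the all-pairs correlation
distribution (one-sided, so strongly positive co-expression); the
differential network (DN) is the treated network minus every edge that also
appears in the untreated network, with isolated nodes dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx

from .errors import DegenerateInputError

log = logging.getLogger(__name__)


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene time series.

    Requires a QC'd matrix: no missing values, no zero-variance rows, and
    at least 3 timepoints.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 timepoints for meaningful correlations")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values; run qc_filter")
    if np.any(values.std(axis=1) == 0):
        bad = expr.index[values.std(axis=1) == 0][0]
        raise ValueError(f"zero-variance series for gene {bad!r}; run qc_filter")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def build_network(corr: pd.DataFrame, quantile: float = 0.995) -> nx.Graph:
    """Threshold a correlation matrix into a co-expression network.

    The cutoff is the empirical ``quantile`` of the upper-triangle
    off-diagonal correlations (each gene pair counted once); edges keep
    pairs with r >= cutoff inclusively, so exact ties at the threshold are
    retained. Nodes left without any edge are excluded. The computed cutoff
    is recorded as ``G.graph["threshold"]``.
    """
    genes = list(corr.index)
    c = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = c[iu, ju]
    if vals.size == 0:
        raise ValueError("correlation matrix has fewer than 2 genes")
    if np.all(vals == vals[0]):
        raise DegenerateInputError(
            "all pairwise correlations are identical; quantile threshold is degenerate"
        )
    q = float(np.quantile(vals, quantile))
    keep = vals >= q
    G = nx.Graph(quantile=quantile, threshold=q)
    for i, j, w in zip(iu[keep], ju[keep], vals[keep]):
        G.add_edge(genes[i], genes[j], weight=float(w))
    log.info(
        "build_network: threshold %.4f at quantile %.4g keeps %d edges over %d nodes",
        q, quantile, G.number_of_edges(), G.number_of_nodes(),
    )
    return G


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edge-set intersection of two replicate networks.

    Membership is by unordered node pair; a surviving edge's weight is the
    mean of the two replicate weights. Singleton nodes are dropped. An empty
    intersection is allowed (returned with a warning).
    """
    G = nx.Graph(**a.graph)
    for u, v, data in a.edges(data=True):
        if b.has_edge(u, v):
            w = (data.get("weight", np.nan) + b[u][v].get("weight", np.nan)) / 2.0
            G.add_edge(u, v, weight=float(w))
    if G.number_of_edges() == 0:
        log.warning("intersect_networks: replicate networks share no edges")
    return G


def differential_network(treated: nx.Graph, untreated: nx.Graph) -> nx.Graph:
    """Treated-only edges: the differential network.

    Keeps each treated edge whose node pair is absent from the untreated
    network (weights are ignored in the membership test; the treated weight
    is carried over). Untreated-only edges are discarded, and so are nodes
    left isolated.
    """
    dn = nx.Graph(**treated.graph)
    for u, v, data in treated.edges(data=True):
        if not untreated.has_edge(u, v):
            dn.add_edge(u, v, **data)
    log.info(
        "differential_network: %d of %d treated edges retained over %d nodes",
        dn.number_of_edges(), treated.number_of_edges(), dn.number_of_nodes(),
    )
    return dn
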