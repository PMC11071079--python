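"""Node-level indices of a partial-correlation network.

Strength is the sum of absolute incident edge weights; expected influence
(EI) keeps the signs, so the two coincide on an all-positive network and EI
drops below strength at nodes with a negative incident edge.  Closeness and
betweenness use the standard symptom-network distance convention: traversing
an edge costs 1/|w|, so strong edges are short.  Predictability is the share
of a node's variance explained by all remaining nodes, estimated here as the
R^2 of an ordinary least-squares regression on the other nodes (a Gaussian
approximation to nodewise predictability).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator

from .ggm import NetworkModel, _as_matrix

__all__ = [
    "strength",
    "expected_influence",
    "node_distances",
    "closeness",
    "betweenness",
    "zscore",
    "centrality_table",
    "predictability",
    "NodePredictability",
]

CENTRALITY_INDICES = ("strength", "expected_influence", "closeness", "betweenness")


def _weights(network: NetworkModel | np.ndarray) -> np.ndarray:
    W = network.weights if isinstance(network, NetworkModel) else np.asarray(network)
    return np.asarray(W, dtype=float)


def strength(network: NetworkModel | np.ndarray) -> np.ndarray:
    """s_i = sum_j |w_ij|."""
    return np.abs(_weights(network)).sum(axis=1)


def expected_influence(network: NetworkModel | np.ndarray) -> np.ndarray:
    """ei_i = sum_j w_ij (signed)."""
    return _weights(network).sum(axis=1)


def node_distances(network: NetworkModel | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/|w|.

    Unreachable pairs get ``inf``; the diagonal is 0.
    """
    W = np.abs(_weights(network))
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    return shortest_path(lengths, method="D", directed=False)


def closeness(network: NetworkModel | np.ndarray) -> np.ndarray:
    """c_i = (p-1) / sum_j d(i, j); 0 for nodes with any unreachable peer."""
    D = node_distances(network)
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = np.delete(D[i], i)
        if np.isinf(d).any() or d.sum() == 0:
            continue
        out[i] = (p - 1) / d.sum()
    return out


def betweenness(network: NetworkModel | np.ndarray) -> np.ndarray:
    """Shortest-path betweenness (1/|w| lengths, fractional credit on ties)."""
    W = _weights(network)
    p = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                G.add_edge(i, j, length=1.0 / abs(W[i, j]))
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(p)])


def zscore(values: np.ndarray) -> np.ndarray:
    """(x - mean) / population SD across nodes; all zeros if constant."""
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0:
        warnings.warn("constant centrality index; z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(
    network: NetworkModel, scores=None, include_z: bool = True
) -> pd.DataFrame:
    """Raw (and z-scored) strength, EI, closeness, betweenness per node,
    plus predictability when the score matrix is supplied."""
    raw = {
        "strength": strength(network),
        "expected_influence": expected_influence(network),
        "closeness": closeness(network),
        "betweenness": betweenness(network),
    }
    table = pd.DataFrame(raw, index=network.node_labels)
    if include_z:
        for name in CENTRALITY_INDICES:
            table[f"z_{name}"] = zscore(table[name].to_numpy())
    if scores is not None:
        table["predictability"] = predictability(scores)
    return table


class NodePredictability(BaseEstimator):
    """Nodewise variance explained.

    For each node, fit an intercept-plus-all-other-nodes least-squares
    regression and record R^2.  Values land in [0, 1]; a node orthogonal to
    the rest gets ~0, an exact linear combination gets 1.

    Attributes
    ----------
    r2_ : (p,) ndarray of per-node R^2
    node_labels_ : list of str
    """

    def fit(self, X, y=None):
        M, labels = _as_matrix(X)
        n, p = M.shape
        if n <= p:
            raise ValueError("need more observations than nodes")
        r2 = np.empty(p)
        for j in range(p):
            yj = M[:, j]
            Xj = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                raise ValueError(f"singular design when predicting node {labels[j]!r}")
            beta, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
            resid = yj - Xj @ beta
            ss_tot = np.sum((yj - yj.mean()) ** 2)
            if ss_tot == 0:
                raise ValueError(f"node {labels[j]!r} is constant")
            r2[j] = 1.0 - np.sum(resid**2) / ss_tot
        self.r2_ = np.clip(r2, 0.0, 1.0)
        self.node_labels_ = labels
        return self


def predictability(scores) -> np.ndarray:
    """Per-node R^2 from regressing each node on all remaining nodes."""
    return NodePredictability().fit(scores).r2_


def analytic_predictability(precision: np.ndarray) -> np.ndarray:
    """Closed-form Gaussian R^2 from a true precision matrix:
    R^2_j = 1 - 1 / (k_jj * sigma_jj)."""
    K = np.asarray(precision, dtype=float)
    sigma = np.linalg.inv(K)
    return 1.0 - 1.0 / (np.diag(K) * np.diag(sigma))
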