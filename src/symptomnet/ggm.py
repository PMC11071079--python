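"""Sparse Gaussian graphical model estimation with EBIC model selection.

The network is a regularized partial-correlation network: nodes are
questionnaire subscales, an edge between two nodes is their partial
correlation controlling for all remaining nodes.  The precision matrix is
estimated by the graphical lasso on the sample correlation matrix over a
log-spaced penalty grid, and the penalty is chosen by the extended BIC

    EBIC(lambda) = -2 logL + E log n + 4 E gamma log p,

with E the number of edges (nonzero off-diagonal pairs) and gamma the
hyperparameter trading fit for sparsity (default 0.5).  Ties are broken
toward the larger penalty, i.e. the sparser model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.base import BaseEstimator

from ._glasso import GlassoConvergenceError, glasso, partial_correlations
from .instrument import SubscaleScoreTable

__all__ = [
    "CorrelationMatrix",
    "GlassoFit",
    "NetworkModel",
    "GraphicalLassoEBIC",
    "correlation_matrix",
    "lambda_grid",
    "glasso_fit",
    "ebic_score",
    "estimate_network",
]


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    method: str
    n_effective: int
    smoothed: bool = False  # True if nearest-PSD smoothing was applied


@dataclass
class GlassoFit:
    lambda_: float
    precision_estimate: np.ndarray
    pcor_estimate: np.ndarray
    loglik: float
    n_edges: int


@dataclass
class NetworkModel:
    """Estimated partial-correlation network with selection metadata."""

    node_labels: list[str]
    weights: np.ndarray  # p x p partial correlations, zero diagonal
    selected_lambda: float
    ebic_gamma: float
    method: str = "pearson"
    n: int = 0

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Nonzero unordered edges as a tidy frame (node_i, node_j, weight)."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append(
                        {
                            "node_i": self.node_labels[i],
                            "node_j": self.node_labels[j],
                            "weight": w,
                        }
                    )
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.node_labels, columns=self.node_labels
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_labels": self.node_labels,
                "weights": self.weights.tolist(),
                "selected_lambda": self.selected_lambda,
                "ebic_gamma": self.ebic_gamma,
                "method": self.method,
                "n": self.n,
                "n_edges": self.n_edges,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        d = json.loads(text)
        return cls(
            node_labels=list(d["node_labels"]),
            weights=np.asarray(d["weights"], dtype=float),
            selected_lambda=float(d["selected_lambda"]),
            ebic_gamma=float(d["ebic_gamma"]),
            method=d.get("method", "pearson"),
            n=int(d.get("n", 0)),
        )


def _as_matrix(scores) -> tuple[np.ndarray, list[str]]:
    if isinstance(scores, SubscaleScoreTable):
        return scores.values(), scores.node_labels
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), [str(c) for c in scores.columns]
    X = np.asarray(scores, dtype=float)
    return X, [f"V{i + 1}" for i in range(X.shape[1])]


def correlation_matrix(scores, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise Pearson or Spearman correlations of the node scores.

    A rank-based matrix can be indefinite; if the smallest eigenvalue is
    negative it is clipped to zero and the matrix rescaled to unit diagonal,
    with the smoothing recorded on the result.
    """
    X, labels = _as_matrix(scores)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} observations, got {n}")
    if np.isnan(X).any():
        raise ValueError("missing values present; apply exclusions first")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise ValueError(f"node {bad!r} is constant; correlation undefined")
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        R = _sps.spearmanr(X).statistic
        R = np.atleast_2d(R)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    smoothed = False
    w = np.linalg.eigvalsh(R)
    if w[0] < -1e-10:
        vals, vecs = np.linalg.eigh(R)
        vals = np.clip(vals, 0.0, None)
        R = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        smoothed = True
    return CorrelationMatrix(R, method, n, smoothed)


def lambda_grid(
    S: CorrelationMatrix | np.ndarray, n_lambda: int = 100, ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max = max |S_ij| down to
    lambda_max * ratio (decreasing)."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    R = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    off = R[~np.eye(R.shape[0], dtype=bool)]
    lam_max = float(np.max(np.abs(off))) if off.size else 0.0
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; degenerate grid")
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def glasso_fit(
    S: CorrelationMatrix | np.ndarray,
    lam: float,
    n: int,
    *,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    warm_start=None,
    return_state: bool = False,
):
    """One graphical-lasso solve; returns the precision, partial
    correlations, Gaussian log-likelihood (additive constants dropped) and
    edge count."""
    R = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    K, W, state = glasso(
        R, lam, tol=tol, max_sweeps=max_sweeps, warm_start=warm_start
    )
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise GlassoConvergenceError("estimated precision is not positive definite")
    loglik = 0.5 * n * (logdet - float(np.sum(R * K)))
    iu = np.triu_indices(R.shape[0], k=1)
    fit = GlassoFit(
        lambda_=float(lam),
        precision_estimate=K,
        pcor_estimate=partial_correlations(K),
        loglik=loglik,
        n_edges=int(np.count_nonzero(K[iu])),
    )
    return (fit, state) if return_state else fit


def ebic_score(fit: GlassoFit, n: int, p: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fit: -2 logL + E log n + 4 E gamma log p."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    E = fit.n_edges
    return -2.0 * fit.loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


class GraphicalLassoEBIC(BaseEstimator):
    """Regularized partial-correlation network estimator.

    Fits graphical-lasso precision matrices over a log-spaced penalty grid
    on the sample correlation matrix and keeps the EBIC-minimizing fit
    (ties broken toward the sparser, larger-penalty model).

    Parameters
    ----------
    gamma : float, default 0.5
        EBIC sparsity hyperparameter.
    method : {"pearson", "spearman"}, default "pearson"
        Input correlation type.
    n_lambda : int, default 100
        Grid size.
    lambda_ratio : float, default 0.01
        Smallest penalty as a fraction of lambda_max.
    tol : float, default 1e-6
        Convergence tolerance on the max parameter change per sweep.
    max_sweeps : int, default 10000

    Attributes
    ----------
    correlation_ : CorrelationMatrix
    precision_ : (p, p) ndarray, selected precision estimate
    weights_ : (p, p) ndarray, selected partial correlations (zero diagonal)
    lambda_ : float, selected penalty
    lambda_grid_ : ndarray of penalties tried (decreasing)
    ebic_ : ndarray of EBIC scores along the grid
    n_edges_path_ : ndarray of edge counts along the grid
    n_edges_ : int
    node_labels_ : list of str
    """

    def __init__(
        self,
        gamma: float = 0.5,
        method: str = "pearson",
        n_lambda: int = 100,
        lambda_ratio: float = 0.01,
        tol: float = 1e-6,
        max_sweeps: int = 10_000,
    ):
        self.gamma = gamma
        self.method = method
        self.n_lambda = n_lambda
        self.lambda_ratio = lambda_ratio
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        _, labels = _as_matrix(X)
        S = correlation_matrix(X, self.method)
        n, p = S.n_effective, S.values.shape[0]
        grid = lambda_grid(S, self.n_lambda, self.lambda_ratio)

        fits: list[GlassoFit] = []
        state = None  # warm start along the path, sparse to dense
        for lam in grid:
            fit, state = glasso_fit(
                S,
                lam,
                n,
                tol=self.tol,
                max_sweeps=self.max_sweeps,
                warm_start=state,
                return_state=True,
            )
            fits.append(fit)

        ebic = np.array([ebic_score(f, n, p, self.gamma) for f in fits])
        # grid is decreasing; argmin returns the first (largest-lambda)
        # minimizer, which is the sparser model on ties
        best = int(np.argmin(ebic))

        self.correlation_ = S
        self.node_labels_ = labels
        self.lambda_grid_ = grid
        self.ebic_ = ebic
        self.n_edges_path_ = np.array([f.n_edges for f in fits])
        self.loglik_ = fits[best].loglik
        self.lambda_ = float(grid[best])
        self.precision_ = fits[best].precision_estimate
        self.weights_ = fits[best].pcor_estimate
        self.n_edges_ = fits[best].n_edges
        self.n_samples_ = n
        return self

    def network_(self) -> NetworkModel:
        """The selected fit as a NetworkModel."""
        return NetworkModel(
            node_labels=self.node_labels_,
            weights=self.weights_,
            selected_lambda=self.lambda_,
            ebic_gamma=self.gamma,
            method=self.method,
            n=self.n_samples_,
        )


def estimate_network(
    scores,
    gamma: float = 0.5,
    method: str = "pearson",
    n_lambda: int = 100,
    ratio: float = 0.01,
) -> NetworkModel:
    """Fit the EBIC graphical lasso and return the selected network."""
    est = GraphicalLassoEBIC(
        gamma=gamma, method=method, n_lambda=n_lambda, lambda_ratio=ratio
    )
    est.fit(scores)
    return est.network_()
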