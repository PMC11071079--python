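"""Accuracy and stability of an estimated network.

Two resampling schemes, both re-running the identical estimation pipeline
(same correlation method, EBIC gamma and penalty grid) on every replicate:

* nonparametric bootstrap — resample participants with replacement at the
  original n; yields empirical confidence intervals around edge weights and
  bootstrapped difference tests for edges and centralities;
* case-dropping bootstrap — subsample without replacement, dropping a fixed
  proportion of participants; feeds the correlation-stability (CS)
  coefficient: the largest drop proportion at which the correlation between
  original and subsample statistics is still >= 0.7 with 95% certainty.
  CS below 0.25 is read as unstable, 0.25-0.5 acceptable, above 0.5 good.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ggm import NetworkModel, _as_matrix, estimate_network
from .metrics import CENTRALITY_INDICES, betweenness, closeness, expected_influence, strength

__all__ = [
    "BootstrapEnsemble",
    "CSResult",
    "NetworkBootstrap",
    "CaseDroppingBootstrap",
    "nonparametric_bootstrap",
    "case_dropping_bootstrap",
    "edge_ci",
    "edge_difference_test",
    "centrality_difference_test",
    "cs_coefficient",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class BootstrapEnsemble:
    """Replicate networks and centralities from one resampling scheme."""

    kind: str  # "nonparametric" | "case_dropping"
    B: int
    seed: int
    node_labels: list[str]
    edge_weights: np.ndarray  # (B_ok, p, p)
    centralities: dict[str, np.ndarray]  # index -> (B_ok, p)
    sample_network: NetworkModel
    drop_proportion: float | None = None
    n_failures: int = 0

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def n_replicates(self) -> int:
        return self.edge_weights.shape[0]

    def _node_index(self, node) -> int:
        if isinstance(node, str):
            return self.node_labels.index(node)
        return int(node)

    def edge_values(self, edge) -> np.ndarray:
        i, j = (self._node_index(v) for v in edge)
        return self.edge_weights[:, i, j]


def _replicate_stats(network: NetworkModel) -> dict[str, np.ndarray]:
    return {
        "strength": strength(network),
        "expected_influence": expected_influence(network),
        "closeness": closeness(network),
        "betweenness": betweenness(network),
    }


def _run_ensemble(X, indices_iter, estimator_kwargs, kind, B, seed, drop=None):
    """Shared replicate loop; failures are recorded, >5% aborts."""
    sample_net = estimate_network(X, **estimator_kwargs)
    M, _ = _as_matrix(X)
    weights, cents, failures = [], {k: [] for k in CENTRALITY_INDICES}, 0
    for idx in indices_iter:
        try:
            net = estimate_network(M[idx], **estimator_kwargs)
        except Exception:
            failures += 1
            continue
        weights.append(net.weights)
        for k, v in _replicate_stats(net).items():
            cents[k].append(v)
    if failures > 0.05 * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed to estimate"
        )
    if failures:
        warnings.warn(f"{failures}/{B} bootstrap replicates failed; skipped")
    return BootstrapEnsemble(
        kind=kind,
        B=B,
        seed=seed,
        node_labels=sample_net.node_labels,
        edge_weights=np.array(weights),
        centralities={k: np.array(v) for k, v in cents.items()},
        sample_network=sample_net,
        drop_proportion=drop,
        n_failures=failures,
    )


class NetworkBootstrap(BaseEstimator):
    """Nonparametric participant bootstrap of the network estimator.

    Parameters mirror :func:`symptomnet.ggm.estimate_network` plus the
    replicate count ``B`` and ``seed``.  ``resample`` is a validation hook:
    a callable ``(rng, n) -> indices`` replacing the default
    with-replacement draw.

    Attributes (after fit): ``ensemble_``, ``network_``.
    """

    def __init__(
        self,
        B: int = 2000,
        seed: int = 0,
        gamma: float = 0.5,
        method: str = "pearson",
        n_lambda: int = 100,
        ratio: float = 0.01,
        resample=None,
    ):
        self.B = B
        self.seed = seed
        self.gamma = gamma
        self.method = method
        self.n_lambda = n_lambda
        self.ratio = ratio
        self.resample = resample

    def _estimator_kwargs(self) -> dict:
        return {
            "gamma": self.gamma,
            "method": self.method,
            "n_lambda": self.n_lambda,
            "ratio": self.ratio,
        }

    def fit(self, X, y=None):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        M, _ = _as_matrix(X)
        n = M.shape[0]
        rng = np.random.default_rng(self.seed)
        draw = self.resample or (lambda r, m: r.integers(0, m, m))
        indices = (draw(rng, n) for _ in range(self.B))
        self.ensemble_ = _run_ensemble(
            X, indices, self._estimator_kwargs(), "nonparametric", self.B, self.seed
        )
        self.network_ = self.ensemble_.sample_network
        return self


class CaseDroppingBootstrap(BaseEstimator):
    """Case-dropping (subsampling) bootstrap over a grid of drop proportions.

    For each proportion q, draws ``B`` subsamples without replacement
    keeping round((1-q) n) participants and re-estimates the network.
    Proportions leaving fewer than p+2 participants are skipped with a
    warning.  q = 0 is allowed as a degenerate validation value (the
    subsample is a permutation of the full sample).

    Attributes (after fit): ``ensembles_`` (one per usable proportion),
    ``network_``, ``centrality_``.
    """

    def __init__(
        self,
        proportions=DEFAULT_PROPORTIONS,
        B: int = 1000,
        seed: int = 0,
        gamma: float = 0.5,
        method: str = "pearson",
        n_lambda: int = 100,
        ratio: float = 0.01,
    ):
        self.proportions = proportions
        self.B = B
        self.seed = seed
        self.gamma = gamma
        self.method = method
        self.n_lambda = n_lambda
        self.ratio = ratio

    def fit(self, X, y=None):
        M, _ = _as_matrix(X)
        n, p = M.shape
        kwargs = {
            "gamma": self.gamma,
            "method": self.method,
            "n_lambda": self.n_lambda,
            "ratio": self.ratio,
        }
        ensembles = []
        for q in self.proportions:
            if not 0 <= q < 1:
                raise ValueError("drop proportions must lie in [0, 1)")
            m = int(round((1 - q) * n))
            if m < p + 2:
                warnings.warn(f"proportion {q} leaves {m} <= p+1 rows; skipped")
                continue
            rng = np.random.default_rng((self.seed, int(round(q * 100))))
            indices = (rng.choice(n, size=m, replace=False) for _ in range(self.B))
            ensembles.append(
                _run_ensemble(X, indices, kwargs, "case_dropping", self.B, self.seed, drop=float(q))
            )
        self.ensembles_ = ensembles
        if ensembles:
            self.network_ = ensembles[0].sample_network
        return self


def nonparametric_bootstrap(
    scores, B: int = 2000, seed: int = 0, pipeline_config: dict | None = None, resample=None
) -> BootstrapEnsemble:
    nb = NetworkBootstrap(B=B, seed=seed, resample=resample, **(pipeline_config or {}))
    return nb.fit(scores).ensemble_


def case_dropping_bootstrap(
    scores,
    proportions=DEFAULT_PROPORTIONS,
    B: int = 1000,
    seed: int = 0,
    pipeline_config: dict | None = None,
) -> list[BootstrapEnsemble]:
    cd = CaseDroppingBootstrap(
        proportions=proportions, B=B, seed=seed, **(pipeline_config or {})
    )
    return cd.fit(scores).ensembles_


def edge_ci(ensemble: BootstrapEnsemble, alpha: float = 0.05) -> pd.DataFrame:
    """Empirical per-edge bootstrap confidence intervals at level 1 - alpha."""
    if ensemble.kind != "nonparametric":
        raise ValueError("edge CIs require a nonparametric ensemble")
    if ensemble.n_replicates < 1.0 / alpha:
        raise ValueError(
            f"B={ensemble.n_replicates} too small for alpha={alpha} quantiles"
        )
    labels = ensemble.node_labels
    W0 = ensemble.sample_network.weights
    rows = []
    for i in range(ensemble.p):
        for j in range(i + 1, ensemble.p):
            vals = ensemble.edge_weights[:, i, j]
            lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
            rows.append(
                {
                    "node_i": labels[i],
                    "node_j": labels[j],
                    "estimate": W0[i, j],
                    "boot_mean": vals.mean(),
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


def _interval_excludes_zero(diffs: np.ndarray, alpha: float) -> bool:
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return lo > 0 or hi < 0


def edge_difference_test(
    ensemble: BootstrapEnsemble, edge_a, edge_b, alpha: float = 0.05
) -> str:
    """"distinct" iff the bootstrap CI of (w_a - w_b) excludes zero."""
    a = tuple(sorted(ensemble._node_index(v) for v in edge_a))
    b = tuple(sorted(ensemble._node_index(v) for v in edge_b))
    if a == b:
        warnings.warn("difference test of an edge against itself")
        return "indistinct"
    diffs = ensemble.edge_values(edge_a) - ensemble.edge_values(edge_b)
    return "distinct" if _interval_excludes_zero(diffs, alpha) else "indistinct"


def centrality_difference_test(
    ensemble: BootstrapEnsemble, node_a, node_b, index: str = "strength", alpha: float = 0.05
) -> str:
    """Bootstrapped difference test for a centrality index of two nodes."""
    ia, ib = ensemble._node_index(node_a), ensemble._node_index(node_b)
    if ia == ib:
        warnings.warn("difference test of a node against itself")
        return "indistinct"
    vals = ensemble.centralities[index]
    return "distinct" if _interval_excludes_zero(vals[:, ia] - vals[:, ib], alpha) else "indistinct"


@dataclass
class CSResult:
    """Correlation-stability coefficient for one statistic."""

    statistic: str
    cs_value: float
    correlation_threshold: float
    certainty_level: float
    quantiles_by_proportion: dict[float, float] = field(default_factory=dict)

    @property
    def interpretation(self) -> str:
        if self.cs_value < 0.25:
            return "unstable"
        if self.cs_value < 0.5:
            return "acceptable"
        return "good"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "cs_value": self.cs_value,
            "correlation_threshold": self.correlation_threshold,
            "certainty_level": self.certainty_level,
            "interpretation": self.interpretation,
            "quantiles_by_proportion": {
                str(k): v for k, v in self.quantiles_by_proportion.items()
            },
        }


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    # a zero-variance vector has no defined correlation; count it as 0
    # (maximally uninformative) rather than NaN
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cs_coefficient(
    ensembles: list[BootstrapEnsemble],
    original,
    statistic: str = "expected_influence",
    threshold: float = 0.7,
    certainty: float = 0.95,
) -> CSResult:
    """Largest tested drop proportion whose (1 - certainty) correlation
    quantile still reaches ``threshold``; 0 when none does.

    ``original`` is the full-sample :class:`NetworkModel` (for
    ``statistic="edge_weights"``) or a centrality table / array of per-node
    values.  Correlations are Pearson over the 8 node values (edge variant:
    over the 28 unordered edge weights).
    """
    if len(ensembles) < 2:
        raise ValueError("need ensembles for at least 2 drop proportions")
    if statistic == "edge_weights":
        p = ensembles[0].p
        iu = np.triu_indices(p, k=1)
        W = original.weights if isinstance(original, NetworkModel) else np.asarray(original)
        ref = W[iu]
        reps = [ens.edge_weights[:, iu[0], iu[1]] for ens in ensembles]
    else:
        if isinstance(original, pd.DataFrame):
            ref = original[statistic].to_numpy()
        else:
            ref = np.asarray(original, dtype=float)
        reps = [ens.centralities[statistic] for ens in ensembles]

    quantiles: dict[float, float] = {}
    for ens, rep in zip(ensembles, reps):
        corrs = np.array([_safe_corr(ref, r) for r in rep])
        quantiles[ens.drop_proportion] = float(
            np.quantile(corrs, 1.0 - certainty)
        )
    qualifying = [q for q, v in quantiles.items() if v >= threshold]
    cs = max(qualifying) if qualifying else 0.0
    return CSResult(
        statistic=statistic,
        cs_value=cs,
        correlation_threshold=threshold,
        certainty_level=certainty,
        quantiles_by_proportion=dict(sorted(quantiles.items())),
    )
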