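"""Synthetic questionnaire data with known ground-truth network structure.

The study's raw data are not public, so every downstream stage is exercised
on simulated data: a sparse, mostly-positive partial-correlation structure
is stated as a precision matrix; latent multivariate-normal draws are pushed
through a Gaussian copula onto bounded-integer subscale supports whose
marginal moments mirror the published descriptives (means ~3.3-8.9, SDs
~2.4-3.6, one negative edge, strongest edges ~0.3).  The generating
precision is kept beside each dataset so estimators can be scored against
truth.

Discretization uses per-node quantile mapping onto a beta-binomial support:
the beta-binomial is the bounded-count family that can hit both the target
mean and the (overdispersed) target SD; when the target SD is at or below
the binomial's, a plain binomial is used.  The mapping is monotone, so
latent and observed ranks agree per node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from ._glasso import partial_correlations
from .ggm import NetworkModel
from .instrument import InstrumentSpec, ItemResponseMatrix, SubscaleScoreTable

__all__ = [
    "PrecisionSpec",
    "MarginalSpec",
    "SyntheticDataset",
    "MHT_REFERENCE_MARGINALS",
    "make_precision_matrix",
    "simulate_subscale_scores",
    "simulate_item_responses",
    "true_network_of",
    "default_fixture_truth",
]


@dataclass
class PrecisionSpec:
    """A ground-truth precision (inverse covariance) matrix."""

    p: int
    precision: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.precision, dtype=float)
        if K.shape != (self.p, self.p):
            raise ValueError("precision shape does not match p")
        if not np.allclose(K, K.T):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(K)[0] <= 0:
            raise ValueError("precision must be positive definite")
        self.precision = K

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def latent_correlation(self) -> np.ndarray:
        S = self.covariance()
        d = np.sqrt(np.diag(S))
        return S / np.outer(d, d)


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal for one node: bounded support and first two moments."""

    name: str
    support_max: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0 < self.mean < self.support_max:
            raise ValueError(f"{self.name}: mean must lie inside (0, support_max)")
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")

    def distribution(self):
        """Frozen scipy distribution on 0..support_max matching the targets.

        Beta-binomial when the target variance exceeds the binomial's at the
        same mean (the usual, overdispersed case), otherwise binomial.
        """
        m, mu = self.support_max, self.mean / self.support_max
        binom_var = m * mu * (1 - mu)
        var = self.sd**2
        if var <= binom_var:
            return _sps.binom(m, mu)
        rho = (var / binom_var - 1.0) / (m - 1.0)
        if rho >= 1.0:
            raise ValueError(f"{self.name}: sd too large for support {m}")
        s = 1.0 / rho - 1.0  # concentration alpha + beta
        return _sps.betabinom(m, mu * s, (1 - mu) * s)


#: Published per-subscale descriptive moments (mean, SD) for the eight MHT
#: content subscales in senior high-school students; supports follow the
#: default instrument layout (15 items for MHT1/MHT6, 10 otherwise).
MHT_REFERENCE_MARGINALS: tuple[MarginalSpec, ...] = (
    MarginalSpec("MHT1", 15, 8.87, 3.60),
    MarginalSpec("MHT2", 10, 5.15, 2.73),
    MarginalSpec("MHT3", 10, 3.63, 2.95),
    MarginalSpec("MHT4", 10, 5.37, 2.97),
    MarginalSpec("MHT5", 10, 6.34, 2.44),
    MarginalSpec("MHT6", 15, 6.68, 3.57),
    MarginalSpec("MHT7", 10, 3.34, 2.74),
    MarginalSpec("MHT8", 10, 3.96, 2.89),
)


@dataclass
class SyntheticDataset:
    scores: pd.DataFrame  # n x p integers
    lie_score: np.ndarray
    truth: PrecisionSpec
    generator_params: dict = field(default_factory=dict)

    def score_table(self) -> SubscaleScoreTable:
        total = self.scores.to_numpy().sum(axis=1)
        return SubscaleScoreTable(
            participant_ids=[f"S{i + 1:04d}" for i in range(len(self.scores))],
            scores=self.scores,
            lie_score=self.lie_score,
            total_score=total,
        )

    def save(self, directory) -> None:
        """Write the scores CSV plus a truth JSON next to it."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from .instrument import write_scores_csv

        write_scores_csv(self.score_table(), directory / "scores.csv")
        truth = {
            "precision": self.truth.precision.tolist(),
            "seed": self.truth.seed,
            "generator_params": self.generator_params,
        }
        (directory / "truth.json").write_text(json.dumps(truth, indent=2))


def make_precision_matrix(
    p: int,
    edge_density: float,
    weight_range: tuple[float, float] = (0.05, 0.35),
    negative_fraction: float = 0.0,
    seed: int = 0,
) -> PrecisionSpec:
    """Random sparse symmetric positive-definite precision matrix.

    Off-diagonal entries are placed on a random subset of pairs with the
    requested density; magnitudes are uniform in ``weight_range`` and a
    ``negative_fraction`` share of edges gets a negative partial correlation
    (positive precision entry; signs flip between precision and partial
    correlation).  The diagonal is set to max(1, 1.1 * row L1 norm) so the
    matrix is strictly diagonally dominant, hence positive definite; when
    row sums stay below 1 the implied partial correlations equal the drawn
    weights exactly.
    """
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    lo, hi = weight_range
    if not (0 < lo <= hi < 1):
        raise ValueError("weight_range must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(edge_density * len(pairs)))
    chosen = rng.permutation(len(pairs))[:n_edges]
    n_neg = int(round(negative_fraction * n_edges))

    K = np.zeros((p, p))
    for rank, idx in enumerate(chosen):
        i, j = pairs[idx]
        w = rng.uniform(lo, hi)
        sign = -1.0 if rank < n_neg else 1.0  # sign of the partial correlation
        K[i, j] = K[j, i] = -sign * w
    rowsum = np.abs(K).sum(axis=1)
    np.fill_diagonal(K, np.maximum(1.0, 1.1 * rowsum))
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise RuntimeError(
            "generated precision is not positive definite; "
            "reduce density or weight magnitudes"
        )
    return PrecisionSpec(p=p, precision=K, seed=seed)


def true_network_of(truth: PrecisionSpec) -> NetworkModel:
    """Ground-truth partial-correlation network implied by the precision."""
    return NetworkModel(
        node_labels=[f"MHT{i + 1}" for i in range(truth.p)],
        weights=partial_correlations(truth.precision),
        selected_lambda=0.0,
        ebic_gamma=float("nan"),
        method="truth",
    )


def default_fixture_truth(seed: int = 2023) -> PrecisionSpec:
    """The package's standard 8-node truth: density 0.6, weights 0.05-0.35,
    one negative edge — the shape of the published network (<=28 edges,
    strongest ~0.3, a single negative edge)."""
    # 17 of 28 pairs at density 0.6; 1/17 edges negative
    return make_precision_matrix(
        p=8,
        edge_density=0.6,
        weight_range=(0.05, 0.35),
        negative_fraction=1.0 / 17.0,
        seed=seed,
    )


def simulate_subscale_scores(
    truth: PrecisionSpec,
    marginals=MHT_REFERENCE_MARGINALS,
    n: int = 625,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw n participants: Gaussian copula on the truth's correlation,
    per-node quantile map onto each marginal's bounded-count distribution.

    The lie score is drawn independently of the content nodes
    (binomial(10, 0.15), almost always below the invalidity window) so
    screening logic can be tested orthogonally.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(marginals) != truth.p:
        raise ValueError("one marginal per node required")
    rng = np.random.default_rng(seed)
    R = truth.latent_correlation()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, truth.p)) @ L.T
    U = _sps.norm.cdf(Z)
    cols = {}
    for k, marg in enumerate(marginals):
        dist = marg.distribution()
        cols[marg.name] = dist.ppf(U[:, k]).astype(int)
    scores = pd.DataFrame(cols)
    lie = rng.binomial(10, 0.15, size=n)
    return SyntheticDataset(
        scores=scores,
        lie_score=lie,
        truth=truth,
        generator_params={
            "n": n,
            "seed": seed,
            "marginals": [
                {"name": m.name, "support_max": m.support_max, "mean": m.mean, "sd": m.sd}
                for m in marginals
            ],
        },
    )


def simulate_item_responses(
    truth: PrecisionSpec,
    spec: InstrumentSpec,
    n: int = 680,
    seed: int = 0,
    n_incomplete: int = 0,
    n_lie_invalid: int = 0,
    latent_loc: float | np.ndarray = 0.0,
) -> ItemResponseMatrix:
    """Item-level fixture: a per-subscale latent propensity drives
    independent Bernoulli items.

    Each participant draws a latent vector from the truth's correlation
    (plus ``latent_loc``); the per-item success probability of subscale k is
    the normal CDF of its latent value, so subscale sums are monotone in the
    latent score.  ``n_incomplete`` rows get one missing entry and
    ``n_lie_invalid`` further rows get a lie score of 8; all remaining rows
    are clamped below the lie-invalidity window so the injected exclusion
    counts are exact.
    """
    if n_incomplete + n_lie_invalid > n:
        raise ValueError("more injected exclusions than rows")
    rng = np.random.default_rng(seed)
    R = truth.latent_correlation()
    L = np.linalg.cholesky(R)
    theta = rng.standard_normal((n, truth.p)) @ L.T + latent_loc
    probs = _sps.norm.cdf(theta)

    X = np.zeros((n, spec.total_items))
    for k, name in enumerate(spec.subscale_names):
        cols = spec.column_indices(name)
        X[:, cols] = rng.binomial(1, probs[:, [k]], size=(n, len(cols)))
    lie_cols = spec.column_indices("lie")
    X[:, lie_cols] = rng.binomial(1, 0.15, size=(n, len(lie_cols)))

    # clamp every lie score below the invalidity window (trim trailing ones)
    for i in range(n):
        ones = lie_cols[X[i, lie_cols] == 1]
        for c in ones[6:]:
            X[i, c] = 0.0

    order = rng.permutation(n)
    incomplete_rows = order[:n_incomplete]
    lie_rows = order[n_incomplete : n_incomplete + n_lie_invalid]
    for i in incomplete_rows:
        X[i, rng.integers(spec.total_items)] = np.nan
    for i in lie_rows:
        X[i, lie_cols] = 0.0
        X[i, lie_cols[:8]] = 1.0  # lie score 8, inside [7, 10]

    ids = [f"S{i + 1:04d}" for i in range(n)]
    return ItemResponseMatrix(ids, X)
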