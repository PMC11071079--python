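# Methods

## Instrument scoring and screening

The MHT is scored 0/1 per item; each of the eight content subscales is the
sum of its items, and the total is the sum of the eight content scores (the
lie scale never enters the total). Screening removes incomplete protocols
first (listwise deletion; no imputation), then protocols with a lie score in
the closed interval [7, 10]; the two causes are counted in that fixed order
so a protocol failing both counts once, as incomplete. Severity grades the
content total as normal (0–55), poor (56–64) or severe (≥65); the boundary
score 65 is graded severe. Subscale flags use ≥8 (clear tendency) and ≤3
(no tendency).

The authentic item-to-subscale key is proprietary, so the default
`InstrumentSpec` ships a stand-in layout: contiguous blocks of 15, 10, 10,
10, 10, 15, 10, 10 items for the eight content subscales (90 items) and the
last 10 items as the lie scale. The 15-item blocks are assigned to the two
subscales whose published means reach ~9, which a 0–10 support could not
accommodate with the published SDs. Users with the real key supply their own
`InstrumentSpec`.

Descriptive statistics use the sample SD (n−1), skewness g1 = m3/m2^1.5 and
excess kurtosis g2 = m4/m2² − 3 (population-moment forms; the excess
convention matches the negative published kurtosis values). A constant
column gets NaN skew/kurtosis deliberately rather than warning-laden
division. Report percentages are rounded to one decimal.

## Network model and estimation

Nodes are the eight subscale scores; the network is a Gaussian graphical
model whose edge weights are partial correlations
ρij = −κij/√(κii·κjj) from the precision matrix K. Estimation maximizes the
L1-penalized Gaussian log-likelihood log det K − tr(SK) − λ·Σ|κij| (diagonal
unpenalized) on the sample correlation matrix S, via block coordinate
descent (columnwise lasso subproblems), written loop-wise and JIT-compiled
with numba. Tolerance is 1e-6 on the maximum parameter change per sweep,
capped at 10,000 sweeps; the penalty path is warm-started from the sparsest
(largest-λ) end, along which the edge count is non-decreasing.

* **Correlation input**: Pearson on subscale sums by default (the scores are
  16- and 11-point counts, close enough to interval scale); Spearman is
  available for ordinal robustness, with eigenvalue-clipping PSD smoothing
  recorded when a rank-based matrix is indefinite.
* **Penalty grid**: 100 log-spaced values from λmax = max|Sij| down to
  0.01·λmax — the standard EBIC-glasso grid.
* **Model selection**: EBIC = −2·logL + E·log n + 4·E·γ·log p with γ = 0.5
  (the conventional compromise between discovery and sparsity); ties break
  toward the larger penalty, i.e. the sparser, more interpretable model.
  The log-likelihood drops additive constants; selection is unaffected.
* **Edge existence**: exact zeros produced by the penalty — no post-hoc
  thresholding. An entry of the symmetrized precision is zero iff both
  columnwise lasso solutions zeroed it.
* λ = 0 is solved by the same algorithm and agrees with the matrix-inverse
  partial correlations on well-conditioned inputs (tested to 1e-4); an
  independent solver (scikit-learn's graphical lasso) is used as a
  cross-check at positive penalties in the tests, never as the
  implementation.

## Centrality and predictability

Strength si = Σj|wij| and expected influence eii = Σj wij are computed on
the selected weights; they coincide unless a node has a negative incident
edge. Closeness and betweenness use edge length 1/|wij| (the standard
symptom-network convention: strong edges are short). Closeness is
(p−1)/Σd(i,j); a node with any unreachable peer scores 0, keeping the index
bounded. Betweenness gives fractional credit across tied shortest paths
(Brandes, via networkx). Z-scores standardize each index across the p nodes
with the population (n-denominator) SD; a constant index z-scores to all
zeros with a warning.

Predictability is the R² of each node regressed (OLS with intercept) on all
remaining nodes — a Gaussian approximation to nodewise predictability; the
mixed-models route used elsewhere in the literature is out of scope. For
Gaussian data the population value is 1 − 1/(κii·σii), which the tests use
as the closed-form target.

## Bootstrap accuracy and stability

Every replicate re-runs the identical estimation pipeline. The
nonparametric bootstrap resamples participants with replacement at the
original n (default B = 2000) and yields percentile CIs per edge
(`np.quantile`, linear interpolation) and difference tests: two edges (or
two nodes' centralities) are "distinct" iff the percentile interval of
their replicate-wise difference excludes zero. Replicate failures are
counted and skipped; more than 5% failing aborts.

The case-dropping bootstrap subsamples without replacement, dropping
proportions 0.05–0.75 in steps of 0.05 (default B = 1000 per proportion).
The CS coefficient for a statistic is the largest tested proportion at
which the 5th percentile (certainty 0.95) of Pearson correlations between
the original and subsample statistic vectors still reaches 0.7; 0 if none
qualifies. A replicate whose statistic vector is constant contributes
correlation 0 (uninformative) rather than NaN. Thresholds 0.7/0.95 and the
grid are configurable; the reported CS is grid-valued, so it can only take
tested proportions.

## Synthetic data: what it emulates and what it does not

The generator states a ground-truth precision matrix: off-diagonal entries
on a random 60% of the 28 node pairs with partial correlations drawn from
(0.05, 0.35) and one negative edge, the diagonal set to
max(1, 1.1 × row L1 norm) so the matrix is strictly diagonally dominant
(hence positive definite); with the default density the row sums stay below
1 and the implied partial correlations equal the drawn weights. This mirrors
the published network's shape — ≤28 edges, strongest weights ≈ 0.3, a
single negative edge.

Scores are drawn through a Gaussian copula: latent multivariate normal with
the truth's correlation, mapped per node by the (monotone) quantile function
of a bounded-count distribution matching the published subscale means and
SDs — beta-binomial where the target is overdispersed relative to the
binomial (every published subscale is), binomial otherwise. The lie score is
simulated independently of the content nodes so screening can be tested
orthogonally. The item-level simulator drives each subscale's items as
independent Bernoulli draws from a per-participant latent propensity and can
inject exact numbers of incomplete and lie-invalid rows (valid rows are
clamped below the lie window so injected counts are exact).

Known limitations of the stated world:

* Discretizing through the copula attenuates Pearson correlations, so
  estimated edge weights and nodewise R² on the discretized scores sit
  systematically ~0.01–0.04 below the latent-Gaussian values; at n = 5000
  this attenuation consumes most of the ±0.05 recovery tolerance, and at
  some seeds the worst node can graze or slightly exceed it. The shipped
  fixtures use the generator's default seeds.
* Items within a subscale are conditionally independent given the latent
  propensity — no item-response-theory structure, no local dependence.
* No demographic covariates, no missingness mechanism beyond injected
  cells, no group differences.

A green test therefore establishes that the pipeline recovers the stated
Gaussian-copula world, not that the MHT's real item process is captured.

## Reproducibility and degenerate inputs

All randomness flows through `numpy.random.default_rng` seeds carried in
configs and function arguments; (input, config, seed) determines every
table byte for byte, and the report manifest records SHA-256 checksums. A
constant node raises a named error at the correlation stage; an
all-independent sample degenerates the penalty grid to a single λ = 0 with
a warning; an empty roster screens to an empty roster with zero counts.
Bootstrap sizes in the test suite are scaled down (B = 50–200, coarser drop
grids) from the production defaults to keep runtimes in minutes; the
affected tests state their scaled tolerances.
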