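"""Bootstrap accuracy, difference tests, and correlation stability."""

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.stability import (
    BootstrapEnsemble,
    case_dropping_bootstrap,
    centrality_difference_test,
    cs_coefficient,
    edge_ci,
    edge_difference_test,
    nonparametric_bootstrap,
)

FAST = {"n_lambda": 30}


@pytest.fixture(scope="module")
def medium_scores(truth):
    return sn.simulate_subscale_scores(truth, n=1000, seed=40).score_table()


@pytest.fixture(scope="module")
def boot(medium_scores):
    return nonparametric_bootstrap(
        medium_scores, B=100, seed=7, pipeline_config=FAST
    )


def identity_resample(rng, n):
    return np.arange(n)


class TestNonparametricBootstrap:
    def test_identity_resample_reproduces_sample_network(self, medium_scores):
        ens = nonparametric_bootstrap(
            medium_scores, B=1, seed=0, pipeline_config=FAST,
            resample=identity_resample,
        )
        np.testing.assert_allclose(
            ens.edge_weights[0], ens.sample_network.weights, atol=1e-12
        )

    def test_same_seed_identical_ensembles(self, medium_scores):
        a = nonparametric_bootstrap(medium_scores, B=10, seed=3, pipeline_config=FAST)
        b = nonparametric_bootstrap(medium_scores, B=10, seed=3, pipeline_config=FAST)
        np.testing.assert_array_equal(a.edge_weights, b.edge_weights)

    def test_bootstrap_mean_recovers_truth(self, truth, large_scores):
        """True-nonzero edges: bootstrap mean within 0.05 of truth (B scaled
        down to 200)."""
        ens = nonparametric_bootstrap(
            large_scores, B=200, seed=5, pipeline_config=FAST
        )
        W_true = sn.true_network_of(truth).weights
        boot_mean = ens.edge_weights.mean(axis=0)
        nz = W_true != 0
        assert np.abs(boot_mean[nz] - W_true[nz]).max() <= 0.05


class TestEdgeCI:
    def test_identical_replicates_zero_width(self, medium_scores):
        ens = nonparametric_bootstrap(
            medium_scores, B=25, seed=0, pipeline_config=FAST,
            resample=identity_resample,
        )
        table = edge_ci(ens, alpha=0.05)
        np.testing.assert_allclose(table["ci_lower"], table["ci_upper"])
        np.testing.assert_allclose(table["ci_lower"], table["estimate"], atol=1e-12)

    def test_quantile_rule_hand_computation(self, boot):
        # fabricate a replicate edge distribution 0.1 .. 1.0 and check the
        # empirical-quantile CI against a hand computation
        ens = BootstrapEnsemble(
            kind="nonparametric",
            B=10,
            seed=0,
            node_labels=boot.node_labels,
            edge_weights=np.array(
                [np.full((8, 8), v) - np.diag(np.full(8, v)) for v in np.arange(0.1, 1.01, 0.1)]
            ),
            centralities=boot.centralities,
            sample_network=boot.sample_network,
        )
        table = edge_ci(ens, alpha=0.2)
        row = table.iloc[0]
        # linear-interpolation quantiles of {0.1..1.0}: q10 = 0.19, q90 = 0.91
        assert row["ci_lower"] == pytest.approx(0.19)
        assert row["ci_upper"] == pytest.approx(0.91)

    def test_estimate_within_replicate_range(self, boot):
        table = edge_ci(boot, alpha=0.05)
        for _, row in table.iterrows():
            vals = boot.edge_values((row["node_i"], row["node_j"]))
            assert vals.min() - 1e-12 <= row["estimate"] <= vals.max() + 1e-12

    def test_ci_contains_bootstrap_median(self, boot):
        table = edge_ci(boot, alpha=0.05)
        for _, row in table.iterrows():
            med = np.median(boot.edge_values((row["node_i"], row["node_j"])))
            assert row["ci_lower"] - 1e-12 <= med <= row["ci_upper"] + 1e-12

    def test_too_few_replicates_rejected(self, medium_scores):
        ens = nonparametric_bootstrap(medium_scores, B=5, seed=1, pipeline_config=FAST)
        with pytest.raises(ValueError):
            edge_ci(ens, alpha=0.05)


class TestDifferenceTests:
    def test_edge_against_itself_indistinct(self, boot):
        with pytest.warns(UserWarning):
            out = edge_difference_test(boot, ("MHT1", "MHT2"), ("MHT2", "MHT1"))
        assert out == "indistinct"

    def test_symmetry(self, boot):
        a, b = ("MHT1", "MHT2"), ("MHT3", "MHT4")
        assert edge_difference_test(boot, a, b) == edge_difference_test(boot, b, a)

    def test_well_separated_edges_distinct(self, truth, large_scores):
        """The strongest and weakest true edges differ far beyond sampling
        noise at n=5000."""
        W = sn.true_network_of(truth).weights
        iu = np.triu_indices(8, k=1)
        nz = [(i, j) for i, j in zip(*iu) if W[i, j] > 0]
        strongest = max(nz, key=lambda e: W[e])
        weakest = min(nz, key=lambda e: W[e])
        ens = nonparametric_bootstrap(
            large_scores, B=100, seed=9, pipeline_config=FAST
        )
        assert edge_difference_test(ens, strongest, weakest) == "distinct"

    def test_node_against_itself_indistinct(self, boot):
        with pytest.warns(UserWarning):
            out = centrality_difference_test(boot, "MHT3", "MHT3")
        assert out == "indistinct"

    def test_star_hub_vs_leaf_distinct_for_strength(self, spec):
        # star truth: hub tied to every leaf, leaves mutually independent
        p = 8
        K = np.eye(p)
        K[0, 1:] = K[1:, 0] = -0.25
        K[0, 0] = 1.1 * np.abs(K[0, 1:]).sum()
        truth = sn.PrecisionSpec(p, K)
        scores = sn.simulate_subscale_scores(truth, n=2000, seed=3).score_table()
        ens = nonparametric_bootstrap(scores, B=50, seed=4, pipeline_config=FAST)
        assert (
            centrality_difference_test(ens, "MHT1", "MHT5", index="strength")
            == "distinct"
        )

    def test_permutation_symmetric_nodes_mostly_indistinct(self):
        """Exchangeable nodes should rarely test distinct (level check,
        scaled to 10 seeded runs)."""
        K = np.eye(3)
        K[0, 1] = K[1, 0] = -0.2  # nodes 0 and 1 exchangeable
        truth = sn.PrecisionSpec(3, K)
        margs = tuple(
            sn.MarginalSpec(f"V{i}", 10, 5.0, 2.5) for i in range(3)
        )
        distinct = 0
        for seed in range(10):
            scores = sn.simulate_subscale_scores(truth, margs, n=400, seed=seed)
            ens = nonparametric_bootstrap(
                scores.score_table(), B=50, seed=100 + seed, pipeline_config=FAST
            )
            if centrality_difference_test(ens, "V0", "V1", "strength") == "distinct":
                distinct += 1
        assert distinct <= 1  # >= 90% indistinct


class TestCaseDropping:
    def test_zero_drop_reproduces_sample(self, medium_scores):
        ens = case_dropping_bootstrap(
            medium_scores, proportions=(0.0, 0.1), B=3, seed=2, pipeline_config=FAST
        )
        zero = next(e for e in ens if e.drop_proportion == 0.0)
        for rep in zero.edge_weights:
            np.testing.assert_allclose(rep, zero.sample_network.weights, atol=1e-12)

    def test_determinism(self, medium_scores):
        a = case_dropping_bootstrap(
            medium_scores, proportions=(0.2, 0.5), B=5, seed=8, pipeline_config=FAST
        )
        b = case_dropping_bootstrap(
            medium_scores, proportions=(0.2, 0.5), B=5, seed=8, pipeline_config=FAST
        )
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.edge_weights, eb.edge_weights)

    def test_tiny_retained_sample_skipped(self, truth):
        scores = sn.simulate_subscale_scores(truth, n=20, seed=1).score_table()
        with pytest.warns(UserWarning):
            ens = case_dropping_bootstrap(
                scores, proportions=(0.1, 0.9), B=2, seed=0, pipeline_config=FAST
            )
        assert [e.drop_proportion for e in ens] == [0.1]

    def test_correlation_declines_with_drop_proportion(self, large_scores):
        """Median subsample-vs-original strength correlations decline
        (weakly) as more cases are dropped."""
        props = (0.1, 0.4, 0.7)
        ens = case_dropping_bootstrap(
            large_scores, proportions=props, B=30, seed=6, pipeline_config=FAST
        )
        original = sn.strength(ens[0].sample_network)
        medians = []
        for e in ens:
            corrs = [
                np.corrcoef(original, rep)[0, 1] for rep in e.centralities["strength"]
            ]
            medians.append(np.median(corrs))
        assert medians[0] >= medians[1] - 0.01 >= medians[2] - 0.02


class TestCSCoefficient:
    def _constant_ensembles(self, boot, props):
        out = []
        for q in props:
            out.append(
                BootstrapEnsemble(
                    kind="case_dropping",
                    B=5,
                    seed=0,
                    node_labels=boot.node_labels,
                    edge_weights=np.repeat(
                        boot.sample_network.weights[None], 5, axis=0
                    ),
                    centralities={
                        k: np.repeat(v[:1], 5, axis=0)
                        for k, v in boot.centralities.items()
                    },
                    sample_network=boot.sample_network,
                    drop_proportion=q,
                )
            )
        return out

    def test_perfectly_stable_statistic(self, boot):
        props = (0.1, 0.3, 0.5, 0.75)
        ens = self._constant_ensembles(boot, props)
        original = boot.centralities["strength"][0]
        res = cs_coefficient(ens, original, "strength")
        assert res.cs_value == 0.75
        assert res.interpretation == "good"

    def test_requires_two_proportions(self, boot):
        with pytest.raises(ValueError):
            cs_coefficient(self._constant_ensembles(boot, (0.1,)), None, "strength")

    def test_monotone_in_threshold_and_certainty(self, large_scores):
        props = (0.1, 0.3, 0.5)
        ens = case_dropping_bootstrap(
            large_scores, proportions=props, B=25, seed=12, pipeline_config=FAST
        )
        net = ens[0].sample_network
        original = sn.strength(net)
        cs_by_threshold = [
            cs_coefficient(ens, original, "strength", threshold=t).cs_value
            for t in (0.5, 0.7, 0.9, 0.999)
        ]
        assert all(a >= b for a, b in zip(cs_by_threshold, cs_by_threshold[1:]))
        cs_by_certainty = [
            cs_coefficient(ens, original, "strength", certainty=c).cs_value
            for c in (0.8, 0.95, 0.999)
        ]
        assert all(a >= b for a, b in zip(cs_by_certainty, cs_by_certainty[1:]))

    def test_edge_weight_variant_runs(self, large_scores):
        ens = case_dropping_bootstrap(
            large_scores, proportions=(0.1, 0.3), B=20, seed=13, pipeline_config=FAST
        )
        res = cs_coefficient(ens, ens[0].sample_network, "edge_weights")
        assert res.cs_value in {0.0, 0.1, 0.3}

    def test_interpretation_labels(self):
        mk = lambda v: sn.stability.CSResult("strength", v, 0.7, 0.95)
        assert mk(0.1).interpretation == "unstable"
        assert mk(0.3).interpretation == "acceptable"
        assert mk(0.6).interpretation == "good"
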