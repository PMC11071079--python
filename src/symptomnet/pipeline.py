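"""End-to-end pipeline: raw responses (or a synthetic spec) to a report
bundle.

Stages run in a fixed order — screening, scoring, descriptives, network
estimation, centrality/predictability, bootstrap accuracy and stability —
and every numeric table is a pure function of (input, config, seed), so a
rerun reproduces the bundle byte for byte.  Output is machine-readable
(CSV/TSV/JSON) plus a manifest with checksums; figure aesthetics are out of
scope, but deterministic force-directed node positions are exported for
plotting elsewhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ggm import NetworkModel, estimate_network
from .instrument import (
    ExclusionReport,
    SubscaleScoreTable,
    apply_exclusions,
    default_instrument_spec,
    descriptive_stats,
    read_responses_csv,
    read_scores_csv,
    score_responses,
)
from .metrics import CENTRALITY_INDICES, centrality_table
from .simulate import (
    MHT_REFERENCE_MARGINALS,
    default_fixture_truth,
    simulate_item_responses,
    simulate_subscale_scores,
)
from .stability import (
    case_dropping_bootstrap,
    centrality_difference_test,
    cs_coefficient,
    edge_ci,
    edge_difference_test,
    nonparametric_bootstrap,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML or JSON.

    ``input_kind`` selects the entry point: "items" (CSV of 0/1 item
    responses, screened and scored first), "scores" (CSV of pre-computed
    subscale scores) or "synthetic" (simulate from the default ground-truth
    fixture).  All stochastic stages derive their streams from ``seed``.
    """

    input_path: str | None = None
    input_kind: str = "synthetic"  # items | scores | synthetic
    n_synthetic: int = 625
    correlation_method: str = "pearson"
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_ratio: float = 0.01
    b_edges: int = 2000
    b_cases: int = 1000
    proportions: tuple = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2).tolist())
    cs_threshold: float = 0.7
    cs_certainty: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "symptomnet_report"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        cfg = cls(**data)
        if cfg.input_kind in ("items", "scores") and not cfg.input_path:
            raise ValueError("input_path required for CSV inputs")
        return cfg

    def estimator_kwargs(self) -> dict:
        return {
            "gamma": self.ebic_gamma,
            "method": self.correlation_method,
            "n_lambda": self.n_lambda,
            "ratio": self.lambda_ratio,
        }

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: PipelineConfig
    exclusion: ExclusionReport | None
    scores: SubscaleScoreTable
    descriptives: pd.DataFrame
    network: NetworkModel
    centrality: pd.DataFrame
    edge_ci_table: pd.DataFrame
    edge_difference: pd.DataFrame
    centrality_difference: dict[str, pd.DataFrame]
    cs_results: dict[str, dict]
    layout: dict[str, list[float]]


def _load_scores(config: PipelineConfig):
    """Resolve the configured input into (scores, exclusion_report)."""
    if config.input_kind == "scores":
        return read_scores_csv(config.input_path), None
    if config.input_kind == "items":
        responses = read_responses_csv(config.input_path)
    elif config.input_kind == "synthetic":
        truth = default_fixture_truth()
        ds = simulate_subscale_scores(
            truth, MHT_REFERENCE_MARGINALS, n=config.n_synthetic, seed=config.seed
        )
        return ds.score_table(), None
    else:
        raise ValueError(f"unknown input_kind {config.input_kind!r}")
    spec = default_instrument_spec()
    kept, report = apply_exclusions(responses, spec)
    return score_responses(kept, spec), report


def _difference_matrix(ensemble, alpha, kind, index=None) -> pd.DataFrame:
    """Upper-triangular matrix of pairwise bootstrapped difference tests."""
    if kind == "edges":
        edges = ensemble.sample_network.edge_list()
        names = [f"{r.node_i}--{r.node_j}" for r in edges.itertuples()]
        pairs = [
            (r.node_i, r.node_j) for r in edges.itertuples()
        ]
        out = pd.DataFrame("", index=names, columns=names)
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                out.iloc[a, b] = edge_difference_test(
                    ensemble, pairs[a], pairs[b], alpha
                )
        return out
    labels = ensemble.node_labels
    out = pd.DataFrame("", index=labels, columns=labels)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            out.iloc[a, b] = centrality_difference_test(
                ensemble, labels[a], labels[b], index, alpha
            )
    return out


def _layout(network: NetworkModel, seed: int) -> dict[str, list[float]]:
    G = nx.Graph()
    G.add_nodes_from(network.node_labels)
    for row in network.edge_list().itertuples():
        G.add_edge(row.node_i, row.node_j, weight=abs(row.weight))
    pos = nx.spring_layout(G, seed=seed)
    return {node: [float(x), float(y)] for node, (x, y) in pos.items()}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and return the assembled bundle."""
    scores, exclusion = _load_scores(config)
    descriptives = descriptive_stats(scores)
    network = estimate_network(scores, **config.estimator_kwargs())
    centrality = centrality_table(network, scores=scores)

    np_ens = nonparametric_bootstrap(
        scores,
        B=config.b_edges,
        seed=config.seed + 1,
        pipeline_config=config.estimator_kwargs(),
    )
    ci_table = edge_ci(np_ens, alpha=config.alpha)
    edge_diff = _difference_matrix(np_ens, config.alpha, "edges")
    cent_diff = {
        idx: _difference_matrix(np_ens, config.alpha, "centrality", idx)
        for idx in ("strength", "expected_influence")
    }

    cd_ens = case_dropping_bootstrap(
        scores,
        proportions=config.proportions,
        B=config.b_cases,
        seed=config.seed + 2,
        pipeline_config=config.estimator_kwargs(),
    )
    cs_results = {}
    for stat in ("strength", "expected_influence"):
        res = cs_coefficient(
            cd_ens,
            centrality,
            statistic=stat,
            threshold=config.cs_threshold,
            certainty=config.cs_certainty,
        )
        cs_results[stat] = res.to_dict()

    return ReportBundle(
        config=config,
        exclusion=exclusion,
        scores=scores,
        descriptives=descriptives,
        network=network,
        centrality=centrality,
        edge_ci_table=ci_table,
        edge_difference=edge_diff,
        centrality_difference=cent_diff,
        cs_results=cs_results,
        layout=_layout(network, config.seed),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(bundle: ReportBundle, outdir) -> dict[str, str]:
    """Write every table plus a checksum manifest; returns {file: sha256}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if bundle.exclusion is not None:
        (outdir / "exclusion_report.json").write_text(
            json.dumps(bundle.exclusion.to_dict(), indent=2)
        )
    bundle.scores.to_frame().to_csv(outdir / "scores.csv", index=False)
    desc = bundle.descriptives.copy()
    for col in ("mean", "sd", "skew", "kurt"):
        desc[col] = desc[col].round(2)
    desc.to_csv(outdir / "descriptives.csv")

    bundle.network.edge_list().to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    bundle.network.to_adjacency_frame().to_csv(outdir / "network_adjacency.csv")
    (outdir / "network.json").write_text(bundle.network.to_json())

    bundle.centrality.to_csv(outdir / "centrality.tsv", sep="\t")
    bundle.edge_ci_table.to_csv(outdir / "edge_ci.tsv", sep="\t", index=False)
    bundle.edge_difference.to_csv(outdir / "edge_difference.tsv", sep="\t")
    for idx, table in bundle.centrality_difference.items():
        table.to_csv(outdir / f"centrality_difference_{idx}.tsv", sep="\t")
    (outdir / "stability.json").write_text(json.dumps(bundle.cs_results, indent=2))
    (outdir / "layout.json").write_text(json.dumps(bundle.layout, indent=2))

    files = sorted(f for f in outdir.iterdir() if f.name != "manifest.json")
    checksums = {f.name: _sha256(f) for f in files}
    manifest = {
        "version": __version__,
        "config": asdict(bundle.config),
        "config_digest": bundle.config.digest(),
        "files": checksums,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return checksums
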