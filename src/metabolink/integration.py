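"""Pipeline core: overlay transition PCA scores and concentration deltas
onto graphical-lasso networks.

The full-dataset network (penalty chosen by cross-validation, fitted
agnostic of stage) provides the global background. For each consecutive
stage pair, a PCA restricted to that pair's samples associates every
metabolite with one of the two stages via its loading on the discriminating
component, a separate GLASSO fit at a fixed penalty (default 0.9; small
per-pair subsets are unstable under cross-validation) yields the
transition-specific edges, and the stage-mean difference gives each node's
concentration delta. The result is an annotated network: background edges
in neutral grey under the colored transition layer, node color = assigned
stage, color intensity = |loading| scaled to [0, 1] within the pair, node
size = |delta|.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import (CovarianceEstimate, PrecisionEstimate, SparseNetwork,
                     cross_validate_alpha, empirical_covariance, graphical_lasso,
                     network_from_precision)
from .io import ConcentrationMatrix, StageSequence
from .pca import PCAResult, TransitionScores, fit_pca, select_discriminant_component, transition_pca
from .preprocess import NormalizedMatrix, stage_means, transition_delta, zscore_normalize

__all__ = ["PipelineConfig", "AnnotatedNetwork", "FullNetworkResult",
           "metabolink_full", "metabolink_transition", "run_all_transitions"]


@dataclass
class PipelineConfig:
    """Tunable settings for a pipeline run; serializable for provenance."""

    n_components: int = 10
    transition_alpha: float = 0.9
    cv_folds: int = 5
    cv_refinements: int = 4
    cv_grid: int = 4
    max_iter: int = 250
    tol: float = 1e-4
    edge_threshold: float = 1e-8
    ddof: int = 0
    rescale_within_pair: bool = False
    restrict_to_background: bool = False
    allow_nonconsecutive: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FullNetworkResult:
    """Full-dataset (stage-agnostic) analysis: background network + global PCA."""

    network: SparseNetwork
    pca: PCAResult
    precision: PrecisionEstimate
    alpha: float
    cv_table: dict[float, float]
    normalized: NormalizedMatrix


@dataclass
class AnnotatedNetwork:
    """One transition's overlay against the background network.

    ``node_attrs`` covers every metabolite (annotated even when isolated):
    assigned_stage, feature_score (signed loading), score_intensity in
    [0, 1] (max-normalized |loading| within the pair), delta_magnitude,
    delta_sign.
    """

    pair: tuple[str, str]
    background_edges: list[tuple[str, str, float]]
    transition_edges: list[tuple[str, str, float]]
    node_attrs: dict[str, dict]
    provenance: dict = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for name, attrs in self.node_attrs.items():
            g.add_node(name, **{k: ("" if v is None else v) for k, v in attrs.items()})
        for a, b, w in self.background_edges:
            g.add_edge(a, b, partial_correlation=w, layer="background")
        for a, b, w in self.transition_edges:
            if g.has_edge(a, b):
                g[a][b]["layer"] = "both"
                g[a][b]["transition_partial_correlation"] = w
            else:
                g.add_edge(a, b, partial_correlation=w, layer="transition")
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.node_attrs, orient="index").rename_axis("metabolite")

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, w, "background") for a, b, w in self.background_edges]
        rows += [(a, b, w, "transition") for a, b, w in self.transition_edges]
        return pd.DataFrame(rows, columns=["source", "target", "partial_correlation", "layer"])


def _fit_background(norm: NormalizedMatrix, config: PipelineConfig):
    alpha, cv_table = cross_validate_alpha(
        norm, n_folds=config.cv_folds, n_refinements=config.cv_refinements,
        n_grid=config.cv_grid, max_iter=config.max_iter, seed=config.seed,
        tol=config.tol,
    )
    est = graphical_lasso(empirical_covariance(norm, ddof=config.ddof), alpha=alpha,
                          tol=config.tol, max_iter=config.max_iter)
    net = network_from_precision(est, norm.metabolite_names, config.edge_threshold)
    return net, est, alpha, cv_table


def metabolink_full(
    data: ConcentrationMatrix,
    stages: StageSequence,
    config: PipelineConfig | None = None,
) -> FullNetworkResult:
    """Stage-agnostic analysis: normalize, full PCA, CV-penalty GLASSO."""
    config = config or PipelineConfig()
    data.validate_against(stages)
    data.require_replicated_stages()
    norm = zscore_normalize(data, ddof=config.ddof)
    k = min(config.n_components, norm.n_samples - 1, norm.n_metabolites)
    pca = fit_pca(norm, n_components=k)
    net, est, alpha, cv_table = _fit_background(norm, config)
    return FullNetworkResult(network=net, pca=pca, precision=est, alpha=alpha,
                             cv_table=cv_table, normalized=norm)


def _transition_overlay(
    norm: NormalizedMatrix,
    stages: StageSequence,
    pair: tuple[str, str],
    background: SparseNetwork,
    config: PipelineConfig,
) -> AnnotatedNetwork:
    a, b = pair
    sub = norm.subset_stages([a, b])
    if config.rescale_within_pair:
        sd = sub.values.std(axis=0, ddof=config.ddof)
        sub.values = sub.values / np.where(sd <= 1e-300, 1.0, sd)
    max_k = min(sub.n_samples - 1, sub.n_metabolites)
    pca = fit_pca(sub, n_components=min(config.n_components, max_k))
    scores = select_discriminant_component(pca, pair)

    est = graphical_lasso(empirical_covariance(sub, ddof=config.ddof),
                          alpha=config.transition_alpha, tol=config.tol,
                          max_iter=config.max_iter)
    pair_net = network_from_precision(est, norm.metabolite_names, config.edge_threshold)
    transition_edges = pair_net.edges
    if config.restrict_to_background:
        bg = background.edge_set()
        transition_edges = [e for e in transition_edges if (e[0], e[1]) in bg]

    means = stage_means(norm, stages)
    delta = transition_delta(means, pair)

    fs = scores.feature_score
    fmax = np.abs(fs).max()
    intensity = np.abs(fs) / fmax if fmax > 0 else np.zeros_like(fs)
    node_attrs = {}
    for j, name in enumerate(norm.metabolite_names):
        d = float(delta[name])
        node_attrs[name] = {
            "assigned_stage": scores.assigned_stage[j],
            "feature_score": float(fs[j]),
            "score_intensity": float(intensity[j]),
            "delta": d,
            "delta_magnitude": abs(d),
            "delta_sign": int(np.sign(d)),
        }
    bg_nodes = set(background.nodes)
    overlap = bg_nodes & {n for e in transition_edges for n in e[:2]}
    provenance = {
        "pair": list(pair),
        "transition_alpha": config.transition_alpha,
        "component_index": scores.component_index,
        "separation": scores.separation,
        "pair_glasso_converged": bool(est.converged),
        "normalization": {"ddof": norm.ddof, "rescale_within_pair": config.rescale_within_pair},
        "background_overlap_empty": len(overlap) == 0,
    }
    return AnnotatedNetwork(
        pair=pair,
        background_edges=list(background.edges),
        transition_edges=transition_edges,
        node_attrs=node_attrs,
        provenance=provenance,
    )


def metabolink_transition(
    data: ConcentrationMatrix,
    pair: tuple[str, str],
    background: SparseNetwork,
    stages: StageSequence,
    config: PipelineConfig | None = None,
) -> AnnotatedNetwork:
    """Build one transition's annotated overlay network.

    ``pair`` must be a consecutive transition of ``stages`` unless the config
    enables non-consecutive pairs.
    """
    config = config or PipelineConfig()
    if pair not in stages.transitions and not config.allow_nonconsecutive:
        raise ValueError(
            f"{pair} is not a consecutive transition of {list(stages.stages)}; "
            "set allow_nonconsecutive to analyze it anyway"
        )
    data.validate_against(stages)
    data.require_replicated_stages()
    norm = zscore_normalize(data, ddof=config.ddof)
    return _transition_overlay(norm, stages, pair, background, config)


def run_all_transitions(
    data: ConcentrationMatrix,
    stages: StageSequence,
    config: PipelineConfig | None = None,
) -> tuple[FullNetworkResult, list[AnnotatedNetwork]]:
    """Full pipeline: one shared background network, one overlay per transition."""
    config = config or PipelineConfig()
    full = metabolink_full(data, stages, config)
    nets = [
        _transition_overlay(full.normalized, stages, pair, full.network, config)
        for pair in stages.transitions
    ]
    return full, nets
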