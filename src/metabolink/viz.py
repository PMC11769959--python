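"""Deterministic figure generation and machine-readable co-exports.

Every numeric value shown in a rendering is also written to a table: network
renders emit a node-coordinates CSV and an edge-style CSV, the heatmap emits
the reordered matrix with its clustering leaf order. The network layout is
computed once on the background graph with a seeded force-directed layout
and reused across all transitions of a run, so panels are comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .integration import AnnotatedNetwork
from .io import StageSequence
from .pca import PCAResult
from .preprocess import NormalizedMatrix

__all__ = ["RenderSpec", "background_layout", "render_network", "render_heatmap",
           "render_pca_scatter"]

_DEFAULT_PALETTE = ("#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
                    "#e6ab02", "#a6761d", "#666666")


@dataclass
class RenderSpec:
    """Styling contract: solid edges = positive partial correlation, dashed =
    negative; line width strictly increasing in |partial correlation|; node
    size affine in the concentration delta magnitude."""

    layout_seed: int = 0
    palette: dict[str, str] = field(default_factory=dict)
    size_range: tuple[float, float] = (60.0, 600.0)
    max_edge_width: float = 4.0
    background_color: str = "#bbbbbb"
    fmt: str = "png"

    def color_for(self, stage: str | None, stages: list[str]) -> str:
        if stage is None or stage == "":
            return self.background_color
        if stage in self.palette:
            return self.palette[stage]
        return _DEFAULT_PALETTE[stages.index(stage) % len(_DEFAULT_PALETTE)]


def background_layout(net: AnnotatedNetwork, spec: RenderSpec) -> dict[str, tuple[float, float]]:
    """Seeded spring layout on the background graph (all annotated nodes)."""
    g = nx.Graph()
    g.add_nodes_from(net.node_attrs)
    g.add_weighted_edges_from(
        (a, b, abs(w)) for a, b, w in net.background_edges
    )
    pos = nx.spring_layout(g, seed=spec.layout_seed)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def _edge_style_rows(edges, layer):
    for a, b, w in edges:
        yield {
            "source": a,
            "target": b,
            "partial_correlation": w,
            "layer": layer,
            "style": "solid" if w >= 0 else "dashed",
            "width": abs(w),
        }


def render_network(
    net: AnnotatedNetwork,
    spec: RenderSpec,
    out_prefix: str | Path,
    stages: list[str],
    coords: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Draw one annotated transition network.

    Writes ``<prefix>.<fmt>`` (image), ``<prefix>.coords.csv`` (node
    positions) and ``<prefix>.edges.csv`` (style table). Returns the
    coordinates used, so callers can reuse them across transitions.
    """
    out_prefix = Path(out_prefix)
    if coords is None:
        coords = background_layout(net, spec)
    pd.DataFrame(
        [(n, x, y) for n, (x, y) in coords.items()], columns=["node", "x", "y"]
    ).to_csv(out_prefix.with_suffix(".coords.csv"), index=False)

    style_rows = list(_edge_style_rows(net.background_edges, "background"))
    style_rows += list(_edge_style_rows(net.transition_edges, "transition"))
    pd.DataFrame(style_rows, columns=["source", "target", "partial_correlation",
                                      "layer", "style", "width"]).to_csv(
        out_prefix.with_suffix(".edges.csv"), index=False)

    fig, ax = plt.subplots(figsize=(8, 8))
    if not net.background_edges and not net.transition_edges:
        warnings.warn(f"empty network for pair {net.pair}; writing empty canvas")
    else:
        dmags = np.array([net.node_attrs[n]["delta_magnitude"] for n in coords])
        dmax = dmags.max() if dmags.size and dmags.max() > 0 else 1.0
        lo, hi = spec.size_range
        sizes = lo + (hi - lo) * dmags / dmax
        for layer, edges, grey in (("background", net.background_edges, True),
                                   ("transition", net.transition_edges, False)):
            for a, b, w in edges:
                xa, ya = coords[a]
                xb, yb = coords[b]
                ax.plot([xa, xb], [ya, yb],
                        linestyle="-" if w >= 0 else "--",
                        linewidth=0.3 + spec.max_edge_width * abs(w),
                        color=spec.background_color if grey
                        else ("#333333" if w >= 0 else "#8888cc"),
                        alpha=0.5 if grey else 0.9, zorder=1 if grey else 2)
        for i, (n, (x, y)) in enumerate(coords.items()):
            attrs = net.node_attrs[n]
            color = spec.color_for(attrs["assigned_stage"], stages)
            ax.scatter([x], [y], s=sizes[i], color=color,
                       alpha=0.25 + 0.75 * attrs["score_intensity"], zorder=3,
                       edgecolors="none")
    ax.set_axis_off()
    ax.set_title(f"{net.pair[0]} → {net.pair[1]}")
    fig.savefig(out_prefix.with_suffix(f".{spec.fmt}"), dpi=150)
    plt.close(fig)
    return coords


def render_heatmap(
    data: NormalizedMatrix,
    stages: StageSequence,
    out_prefix: str | Path,
) -> list[str]:
    """Stage-grouped heatmap with hierarchically clustered metabolites.

    Samples are grouped by stage in sequence order; metabolite order comes
    from average-linkage hierarchical clustering on Euclidean distances.
    Writes ``<prefix>.png`` and the reordered matrix ``<prefix>.csv``;
    returns the metabolite leaf order.
    """
    out_prefix = Path(out_prefix)
    sample_order = [i for s in stages.stages
                    for i in range(data.n_samples) if data.stage_labels[i] == s]
    X = data.values[sample_order]
    if data.n_metabolites > 1:
        Z = linkage(data.values.T, method="average", metric="euclidean")
        leaf_order = [int(i) for i in leaves_list(Z)]
    else:
        leaf_order = [0]
    names = [data.metabolite_names[j] for j in leaf_order]
    ordered = pd.DataFrame(
        X[:, leaf_order],
        index=[data.sample_ids[i] for i in sample_order],
        columns=names,
    )
    ordered.to_csv(out_prefix.with_suffix(".csv"))

    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(ordered.values.T, aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xlabel("samples (grouped by stage)")
    ax.set_ylabel("metabolites (clustered)")
    fig.colorbar(im, ax=ax, label="normalized abundance")
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
    plt.close(fig)
    return names


def render_pca_scatter(
    pca: PCAResult,
    stages: StageSequence,
    out_prefix: str | Path,
    spec: RenderSpec | None = None,
) -> pd.DataFrame:
    """3-D scatter of the first three PCA scores, plus plain coordinates CSV."""
    spec = spec or RenderSpec()
    out_prefix = Path(out_prefix)
    k = min(3, pca.n_components)
    cols = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(pca.scores[:, :k], columns=cols,
                          index=pd.Index(pca.sample_ids, name="sample"))
    coords["stage"] = pca.stage_labels
    coords.to_csv(out_prefix.with_suffix(".csv"))

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d") if k == 3 else fig.add_subplot()
    for stage in stages.stages:
        sub = coords[coords["stage"] == stage]
        xyz = [sub[c] for c in cols]
        ax.scatter(*xyz, label=stage,
                   color=spec.color_for(stage, list(stages.stages)))
    ax.legend()
    fig.savefig(out_prefix.with_suffix(f".{spec.fmt}"), dpi=150)
    plt.close(fig)
    return coords
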