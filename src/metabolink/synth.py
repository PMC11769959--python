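"""Synthetic longitudinal metabolomics data with known ground truth.

The generator emulates the structure the pipeline assumes: k ordered cell
stages, n replicates per stage, and p features drawn from a multivariate
Gaussian whose sparse precision matrix (hence conditional-independence
graph) is planted and recorded, with stage-specific mean shifts on planted
marker sets. Every downstream claim (support recovery, marker recovery,
overlay semantics) is testable against this recorded truth.

The Gaussian model is the natural choice because the graphical-lasso
likelihood is Gaussian; an optional positivity transform exists for
realism, but the pipeline standardizes columns anyway so the default output
is raw Gaussian.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ConcentrationMatrix, StageSequence

__all__ = [
    "SyntheticTruth",
    "generate_precision",
    "make_truth",
    "plant_markers",
    "generate_dataset",
    "default_classes",
    "round_robin_annotation",
]

default_classes = (
    "amino acids", "bioenergetics", "peptides", "carbohydrates",
    "lipids", "organic acids", "amines", "nucleosides",
)


@dataclass
class SyntheticTruth:
    """Planted generative model: precision support, stage means, markers."""

    theta_true: np.ndarray
    support: set[tuple[int, int]]
    stage_means: np.ndarray  # (k, p), in within-stage sd units
    stages: StageSequence
    metabolite_names: list[str]
    marker_sets: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def p(self) -> int:
        return self.theta_true.shape[0]

    def covariance(self) -> np.ndarray:
        C = np.linalg.inv(self.theta_true)
        return (C + C.T) / 2.0


def generate_precision(
    p: int, density: float, seed: int
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Sparse positive-definite precision with Erdos-Renyi support.

    Off-diagonal magnitudes are uniform in [0.1, 0.4] with random sign; the
    diagonal is boosted to (absolute row sum + 0.5), giving strict diagonal
    dominance and hence positive definiteness for any seed.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    theta = np.zeros((p, p))
    support: set[tuple[int, int]] = set()
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                mag = rng.uniform(0.1, 0.4)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                theta[i, j] = theta[j, i] = sign * mag
                support.add((i, j))
    row_abs = np.abs(theta).sum(axis=1)
    np.fill_diagonal(theta, row_abs + 0.5)
    return theta, support


def make_truth(
    p: int,
    stages: StageSequence,
    density: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """Convenience constructor: planted precision, zero stage means."""
    theta, support = generate_precision(p, density, seed)
    names = [f"M{j + 1:03d}" for j in range(p)]
    return SyntheticTruth(
        theta_true=theta,
        support=support,
        stage_means=np.zeros((len(stages), p)),
        stages=stages,
        metabolite_names=names,
        seed=seed,
    )


def plant_markers(
    truth: SyntheticTruth,
    transition: tuple[str, str],
    markers: list[str],
    shift: float,
) -> SyntheticTruth:
    """Plant a persistent (step) mean shift for marker metabolites.

    ``shift`` is in within-stage standard-deviation units and is added to the
    later stage of the transition and every stage after it, so the profile is
    a step at the transition. Returns a new truth; the input is unchanged.
    """
    if transition not in truth.stages.transitions:
        raise ValueError(f"{transition} is not a consecutive transition of {truth.stages.stages}")
    unknown = [m for m in markers if m not in truth.metabolite_names]
    if unknown:
        raise ValueError(f"unknown markers: {unknown}")
    means = truth.stage_means.copy()
    b_idx = truth.stages.index(transition[1])
    cols = [truth.metabolite_names.index(m) for m in markers]
    for s in range(b_idx, len(truth.stages)):
        means[s, cols] += shift
    marker_sets = dict(truth.marker_sets)
    marker_sets[transition] = list(markers)
    return replace(truth, stage_means=means, marker_sets=marker_sets)


def generate_dataset(
    truth: SyntheticTruth,
    n_rep: int,
    seed: int,
    transform: str = "none",
) -> ConcentrationMatrix:
    """Draw n_rep samples per stage from the planted Gaussian model.

    Stage means (given in within-stage sd units) are scaled by each feature's
    marginal sd so a shift of 2 is a 2-sigma effect regardless of the planted
    covariance. ``transform="exp"`` exponentiates to strictly positive
    values; ``"shift"`` adds a constant making the minimum 1; the default
    leaves raw Gaussian values (downstream standardization removes scale).
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    cov = truth.covariance()
    sds = np.sqrt(np.diag(cov))
    L = np.linalg.cholesky(cov)
    blocks, sample_ids, stage_labels, replicate_ids = [], [], [], []
    for s_idx, stage in enumerate(truth.stages.stages):
        noise = rng.standard_normal((n_rep, truth.p)) @ L.T
        X = noise + truth.stage_means[s_idx] * sds
        blocks.append(X)
        for r in range(n_rep):
            sample_ids.append(f"{stage}_r{r + 1}")
            stage_labels.append(stage)
            replicate_ids.append(str(r + 1))
    values = np.vstack(blocks)
    if transform == "exp":
        values = np.exp(values / 2.0)
    elif transform == "shift":
        values = values - values.min() + 1.0
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return ConcentrationMatrix(
        values=values,
        sample_ids=sample_ids,
        stage_labels=stage_labels,
        replicate_ids=replicate_ids,
        metabolite_names=list(truth.metabolite_names),
    )


def round_robin_annotation(names: list[str], classes=default_classes) -> dict[str, str]:
    """Assign compound classes round-robin (for synthetic annotation tables)."""
    return {n: classes[i % len(classes)] for i, n in enumerate(names)}
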