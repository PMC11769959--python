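"""Column standardization and stage-level summaries.

Everything downstream (PCA, covariance estimation, the network overlay, the
pattern screen) consumes the mean- and stddev-normalized matrix produced
here. Normalization is computed once on the full dataset; per-transition
analyses re-center on their sample subset but reuse the global scaling by
default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConcentrationMatrix, StageSequence

__all__ = ["NormalizedMatrix", "zscore_normalize", "stage_means", "transition_delta"]


@dataclass
class NormalizedMatrix:
    """Column-standardized data plus the statistics used to produce it.

    Each column has mean 0 and sd 1 except columns that were constant in the
    raw data: those are kept (as all-zero columns, flagged in
    ``constant_mask``) so metabolite indices stay aligned with the network.
    """

    values: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    constant_mask: np.ndarray
    metabolite_names: list[str]
    sample_ids: list[str]
    stage_labels: list[str]
    replicate_ids: list[str]
    ddof: int = 0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def stage_mask(self, stage: str) -> np.ndarray:
        return np.array([s == stage for s in self.stage_labels], dtype=bool)

    def subset_stages(self, keep) -> "NormalizedMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.stage_labels) if s in keep_set]
        return NormalizedMatrix(
            values=self.values[idx],
            feature_means=self.feature_means,
            feature_sds=self.feature_sds,
            constant_mask=self.constant_mask,
            metabolite_names=list(self.metabolite_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            stage_labels=[self.stage_labels[i] for i in idx],
            replicate_ids=[self.replicate_ids[i] for i in idx],
            ddof=self.ddof,
        )

    def stats_dict(self) -> dict:
        """Normalization statistics, JSON-serializable, for provenance."""
        return {
            "ddof": self.ddof,
            "feature_means": dict(zip(self.metabolite_names, map(float, self.feature_means))),
            "feature_sds": dict(zip(self.metabolite_names, map(float, self.feature_sds))),
            "constant_features": [m for m, c in zip(self.metabolite_names, self.constant_mask) if c],
        }


def zscore_normalize(data: ConcentrationMatrix, ddof: int = 0) -> NormalizedMatrix:
    """Standardize each metabolite to mean 0 and sd 1.

    ``ddof=0`` (population sd) is the default convention; ``ddof=1`` gives the
    sample sd. Constant columns become all-zero and are flagged rather than
    dropped.
    """
    if data.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    X = data.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    # max == min is the robust constancy check: for a column of identical
    # large values, rounding in the mean can make np.std spuriously nonzero
    constant = (X.max(axis=0) == X.min(axis=0)) | (sds == 0)
    safe = np.where(constant, 1.0, sds)
    Z = (X - means) / safe
    Z[:, constant] = 0.0
    return NormalizedMatrix(
        values=Z,
        feature_means=means,
        feature_sds=np.where(constant, 0.0, sds),
        constant_mask=constant,
        metabolite_names=list(data.metabolite_names),
        sample_ids=list(data.sample_ids),
        stage_labels=list(data.stage_labels),
        replicate_ids=list(data.replicate_ids),
    )


def stage_means(data: NormalizedMatrix, stages: StageSequence) -> pd.DataFrame:
    """Stage x metabolite matrix of arithmetic means of normalized values."""
    rows = {}
    for stage in stages.stages:
        mask = data.stage_mask(stage)
        if not mask.any():
            raise ValueError(f"stage {stage!r} has no samples")
        rows[stage] = data.values[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=data.metabolite_names)


def transition_delta(means: pd.DataFrame, pair: tuple[str, str]) -> pd.Series:
    """Signed per-metabolite concentration change over a transition.

    delta(m) = mean_b(m) - mean_a(m); the overlay consumes |delta| for node
    size and the sign for direction. Antisymmetric under swapping the pair.
    """
    a, b = pair
    for s in (a, b):
        if s not in means.index:
            raise ValueError(f"stage {s!r} not present in stage means")
    return means.loc[b] - means.loc[a]
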