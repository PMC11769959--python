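"""Template pattern screening and all-pairs feature correlation.

A pattern template is a dash-separated series of numbers, one per stage in
biological order, describing the expected relative concentration profile:
"1-2-3-4-5" screens for monotone increase over five stages, "2-1-1-1-1" for
elevation only in the first stage. Each metabolite is scored by the
correlation between its per-sample values and the template level of the
sample's stage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConcentrationMatrix, StageSequence
from .preprocess import NormalizedMatrix

__all__ = ["PatternTemplate", "parse_template", "pattern_hunter", "correlation_matrix"]


@dataclass(frozen=True)
class PatternTemplate:
    levels: tuple[float, ...]
    stages: tuple[str, ...]

    def level_for(self, stage: str) -> float:
        return self.levels[self.stages.index(stage)]


def parse_template(spec: str, stages: StageSequence) -> PatternTemplate:
    """Parse a dash-separated template string aligned to the stage order."""
    tokens = [t.strip() for t in spec.split("-")]
    if len(tokens) != len(stages):
        raise ValueError(
            f"template {spec!r} has {len(tokens)} levels; expected {len(stages)} "
            f"(one per stage)"
        )
    try:
        levels = tuple(float(t) for t in tokens)
    except ValueError as exc:
        raise ValueError(f"non-numeric template level in {spec!r}") from exc
    if len(set(levels)) == 1:
        raise ValueError("constant template carries no pattern")
    return PatternTemplate(levels=levels, stages=tuple(stages.stages))


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan, np.nan
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if n < 3:
        return r, 1.0
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def pattern_hunter(
    data: ConcentrationMatrix,
    template: PatternTemplate,
    mode: str = "samples",
    fdr: bool = False,
) -> pd.DataFrame:
    """Correlate every metabolite with a stage-indexed template.

    mode="samples" (default) assigns each sample its stage's template level,
    so replicate variance penalizes noisy matches; mode="stage_means"
    correlates per-stage mean profiles with the template instead.

    Returns a DataFrame indexed by metabolite with columns r, p_value,
    sign_class (positive/negative/undefined) and constant (flag), sorted by
    |r| descending; with ``fdr=True`` a Benjamini-Hochberg q_value column is
    appended.
    """
    missing = [s for s in template.stages if not data.stage_mask(s).any()]
    if missing:
        raise ValueError(f"stages without samples: {missing}")
    if mode == "samples":
        y = np.array([template.level_for(s) for s in data.stage_labels])
        X = data.values
        if len(y) < 3:
            raise ValueError("pattern screening needs at least 3 samples")
    elif mode == "stage_means":
        y = np.asarray(template.levels, dtype=float)
        X = np.vstack(
            [data.values[data.stage_mask(s)].mean(axis=0) for s in template.stages]
        )
        if len(y) < 3:
            raise ValueError("stage-mean mode needs at least 3 stages")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for j, name in enumerate(data.metabolite_names):
        r, p = _pearson_with_p(X[:, j], y)
        constant = np.isnan(r)
        if constant:
            r, p = 0.0, 1.0
        sign_class = "positive" if r > 0 else ("negative" if r < 0 else "undefined")
        rows.append((name, r, p, sign_class, constant))
    out = pd.DataFrame(rows, columns=["metabolite", "r", "p_value", "sign_class", "constant"])
    out = out.set_index("metabolite")
    if fdr:
        out["q_value"] = _benjamini_hochberg(out["p_value"].values)
    return out.sort_values("r", key=np.abs, ascending=False, kind="stable")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q


def correlation_matrix(
    data: NormalizedMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """All-pairs Pearson correlation of metabolites.

    Returns (matrix, constant_features); constant features get zero
    off-diagonal entries and unit diagonal.
    """
    X = data.values
    n, p = X.shape
    if n < 3:
        raise ValueError("correlation matrix needs at least 3 samples")
    sd = X.std(axis=0)
    constant = sd <= 1e-300
    Xc = X - X.mean(axis=0)
    safe = np.where(constant, 1.0, sd)
    Z = Xc / safe
    C = Z.T @ Z / n
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    names = data.metabolite_names
    flags = [names[j] for j in range(p) if constant[j]]
    return pd.DataFrame(C, index=names, columns=names), flags
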