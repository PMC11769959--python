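"""PCA via singular value decomposition with a deterministic sign convention.

Two usage modes: a single PCA over the full standardized dataset (for the
global score scatter), and one PCA per consecutive stage pair. The pairwise
mode turns the five-way stage classification into a sequence of binary ones,
so each metabolite's loading on the discriminating component associates it
with one of the two stages of the transition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedMatrix

__all__ = ["PCAResult", "TransitionScores", "fit_pca", "transition_pca",
           "select_discriminant_component"]


@dataclass
class PCAResult:
    """SVD-based PCA decomposition.

    loadings: (p, k) with orthonormal columns; scores: (n, k) equal to the
    centered data projected on the loadings; explained_variance uses the
    ddof=1 convention so it sums to the total sample variance.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    mean_: np.ndarray
    metabolite_names: list[str]
    sample_ids: list[str]
    stage_labels: list[str]


@dataclass
class TransitionScores:
    """Feature association for one stage transition.

    ``feature_score`` is the signed loading of each metabolite on the selected
    component, oriented so the later stage's samples have the larger mean
    score; a positive loading therefore associates the metabolite with
    ``pair[1]``, a negative one with ``pair[0]``.
    """

    pair: tuple[str, str]
    component_index: int
    feature_score: np.ndarray
    assigned_stage: list[str | None]
    separation: float
    metabolite_names: list[str]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-|.| loading entry is positive."""
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]


def fit_pca(data: NormalizedMatrix, n_components: int = 10) -> PCAResult:
    X = data.values
    n, p = X.shape
    max_k = min(n - 1, p)
    if n_components > max_k:
        raise ValueError(
            f"n_components={n_components} too large; admissible maximum is {max_k}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; components are rows of Vt
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev_all = s**2 / (n - 1)
    total_var = ev_all.sum()
    k = n_components
    loadings = Vt[:k].T.copy()
    scores = Xc @ loadings
    _fix_signs(loadings, scores)
    ratio = ev_all[:k] / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance=ev_all[:k],
        explained_variance_ratio=ratio,
        n_components=k,
        mean_=mean,
        metabolite_names=list(data.metabolite_names),
        sample_ids=list(data.sample_ids),
        stage_labels=list(data.stage_labels),
    )


def transition_pca(
    data: NormalizedMatrix,
    pair: tuple[str, str],
    n_components: int | None = None,
    rescale: bool = False,
) -> PCAResult:
    """PCA restricted to the samples of one stage pair.

    The subset is re-centered; by default it keeps the global per-metabolite
    scaling (``rescale=True`` re-standardizes within the pair).
    """
    a, b = pair
    for s in pair:
        if sum(data.stage_mask(s)) < 2:
            raise ValueError(f"stage {s!r} needs at least 2 samples for pair PCA")
    sub = data.subset_stages([a, b])
    if rescale:
        sd = sub.values.std(axis=0, ddof=data.ddof)
        sd = np.where(sd <= 1e-300, 1.0, sd)
        sub.values = sub.values / sd
    max_k = min(sub.n_samples - 1, sub.n_metabolites)
    k = max_k if n_components is None else min(n_components, max_k)
    return fit_pca(sub, n_components=k)


def select_discriminant_component(
    result: PCAResult, pair: tuple[str, str]
) -> TransitionScores:
    """Pick the component that best separates the two stages and orient it.

    Separation of component c is |mean score(b) - mean score(a)| divided by
    the pooled within-stage score sd; ties fall back to the lowest component
    index. The component is flipped if needed so stage b's mean score is >=
    stage a's, then each metabolite is assigned to b (positive loading) or a
    (negative loading).
    """
    a, b = pair
    labels = np.asarray(result.stage_labels)
    present = set(labels)
    if present != {a, b}:
        raise ValueError(f"expected exactly stages {pair}, found {sorted(present)}")
    mask_a = labels == a
    mask_b = labels == b
    na, nb = int(mask_a.sum()), int(mask_b.sum())

    sep = np.empty(result.n_components)
    diffs = np.empty(result.n_components)
    for c in range(result.n_components):
        sc = result.scores[:, c]
        d = sc[mask_b].mean() - sc[mask_a].mean()
        va = sc[mask_a].var(ddof=1) if na > 1 else 0.0
        vb = sc[mask_b].var(ddof=1) if nb > 1 else 0.0
        pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
        diffs[c] = d
        if pooled > 0:
            sep[c] = abs(d) / pooled
        else:
            sep[c] = np.inf if d != 0 else 0.0
    if np.all(sep == 0):
        raise ValueError("degenerate data: zero separation on every component")
    c_best = int(np.argmax(sep))

    orient = 1.0 if diffs[c_best] >= 0 else -1.0
    feature_score = orient * result.loadings[:, c_best]
    assigned: list[str | None] = [
        b if f > 0 else (a if f < 0 else None) for f in feature_score
    ]
    return TransitionScores(
        pair=pair,
        component_index=c_best,
        feature_score=feature_score,
        assigned_stage=assigned,
        separation=float(sep[c_best]),
        metabolite_names=list(result.metabolite_names),
    )
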