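"""Graphical lasso: L1-penalized sparse precision estimation.

The estimator maximizes the penalized Gaussian log-likelihood

    log det(Theta) - tr(S Theta) - alpha * sum_{i != j} |Theta_ij|

by blockwise coordinate descent on the working covariance W: each
row/column subproblem is an L1-regularized quadratic solved by cyclic
coordinate descent, and the running precision matrix is maintained through
the partitioned-inverse identities. Convergence is declared when the duality
gap falls below ``tol``. The penalty applies to off-diagonal entries only by
default (the diagonal carries no sparsity interpretation); a flag enables
the full-matrix penalty.

A zero off-diagonal precision entry means conditional independence of the
two metabolites given all others; nonzero entries become network edges
weighted by the partial correlation -Theta_ij / sqrt(Theta_ii * Theta_jj).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import NormalizedMatrix

__all__ = [
    "CovarianceEstimate",
    "PrecisionEstimate",
    "SparseNetwork",
    "empirical_covariance",
    "graphical_lasso",
    "cross_validate_alpha",
    "network_from_precision",
    "penalized_loglik",
    "duality_gap",
]


# ---------------------------------------------------------------------------
# inner lasso kernel (numba-jitted when available)

def _lasso_cd(W11, s12, beta, alpha, tol, max_iter):
    """Cyclic coordinate descent for 0.5 b'W11 b - s12'b + alpha*|b|_1."""
    m = s12.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(m):
            old = beta[k]
            r = s12[k]
            for l in range(m):
                if l != k:
                    r -= W11[k, l] * beta[l]
            if r > alpha:
                bk = (r - alpha) / W11[k, k]
            elif r < -alpha:
                bk = (r + alpha) / W11[k, k]
            else:
                bk = 0.0
            beta[k] = bk
            d = abs(bk - old)
            if d > dmax:
                dmax = d
        if dmax < tol:
            break
    return beta


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _lasso_cd = njit(cache=False)(_lasso_cd)
except Exception:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# data types

@dataclass
class CovarianceEstimate:
    """Empirical covariance of standardized data (correlation-like)."""

    S: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        self.S = (S + S.T) / 2.0

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass
class PrecisionEstimate:
    """GLASSO output: sparse precision, its inverse, and solver diagnostics."""

    theta: np.ndarray
    W: np.ndarray
    alpha: float
    n_iter: int
    gap: float
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.theta))
        P = -self.theta / np.outer(d, d)
        np.fill_diagonal(P, 1.0)
        return P


@dataclass
class SparseNetwork:
    """Partial-correlation network; isolated nodes are excluded.

    ``edges`` holds (name_i, name_j, partial_correlation) with i < j in the
    input metabolite order; ``nodes`` keeps input order.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for n in self.nodes:
            h.update(n.encode())
        for a, b, w in self.edges:
            h.update(f"{a}|{b}|{w!r}".encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# operations

def empirical_covariance(data: NormalizedMatrix | np.ndarray, ddof: int = 0) -> CovarianceEstimate:
    """S = Xc' Xc / (n - ddof) on centered data.

    For globally standardized data (population sd) the diagonal is exactly 1.
    """
    X = data.values if isinstance(data, NormalizedMatrix) else np.asarray(data, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("covariance needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - ddof)
    S = (S + S.T) / 2.0
    return CovarianceEstimate(S=S, n_samples=n)


def penalized_loglik(theta: np.ndarray, S: np.ndarray, alpha: float,
                     penalize_diagonal: bool = False) -> float:
    """log det Theta - tr(S Theta) - alpha * |Theta|_1 (off-diagonal by default)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    l1 = np.abs(theta).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(theta)).sum()
    return logdet - float(np.sum(S * theta)) - alpha * l1


def duality_gap(theta: np.ndarray, S: np.ndarray, alpha: float,
                penalize_diagonal: bool = False) -> float:
    """Surrogate duality gap tr(S Theta) - p + alpha * |Theta|_1,off; 0 at optimum."""
    p = S.shape[0]
    l1 = np.abs(theta).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(theta)).sum()
    return float(np.sum(S * theta)) - p + alpha * l1


def _check_psd(S: np.ndarray, tol: float = 1e-10) -> None:
    w = np.linalg.eigvalsh(S)
    if w.min() < -tol:
        raise ValueError(f"S is not positive semidefinite (min eigenvalue {w.min():.3e})")


def graphical_lasso(
    S: CovarianceEstimate | np.ndarray,
    alpha: float,
    tol: float = 1e-4,
    max_iter: int = 250,
    penalize_diagonal: bool = False,
    inner_tol: float = 1e-7,
    inner_max_iter: int = 1000,
) -> PrecisionEstimate:
    """Solve the graphical lasso at penalty ``alpha``.

    Returns the precision matrix ``theta`` (exactly symmetric, positive
    definite) and its inverse ``W``; ``converged`` reports whether the duality
    gap fell below ``tol`` within ``max_iter`` sweeps.
    """
    if isinstance(S, CovarianceEstimate):
        Smat = S.S
    else:
        Smat = np.asarray(S, dtype=float)
        if not np.allclose(Smat, Smat.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        Smat = (Smat + Smat.T) / 2.0
        _check_psd(Smat)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = Smat.shape[0]

    if alpha == 0:
        if np.linalg.cond(Smat) > 1e12:
            raise ValueError("alpha=0 requires a nonsingular covariance")
        theta = np.linalg.inv(Smat)
        theta = (theta + theta.T) / 2.0
        obj = penalized_loglik(theta, Smat, 0.0)
        return PrecisionEstimate(theta=theta, W=Smat.copy(), alpha=0.0, n_iter=0,
                                 gap=0.0, converged=True, objective_history=[obj])

    # init: keep the diagonal exact, shrink off-diagonals slightly for PD safety
    W = Smat * 0.95
    np.fill_diagonal(W, np.diag(Smat))
    if penalize_diagonal:
        W[np.diag_indices_from(W)] += alpha
    theta = np.linalg.pinv(W)
    B = np.zeros((p, p))  # B[:, j] holds the lasso coefficients of column j

    idx_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    history: list[float] = []
    gap = np.inf
    converged = False
    n_iter = 0
    for sweep in range(max_iter):
        for j in range(p):
            idx = idx_cache[j]
            W11 = np.ascontiguousarray(W[np.ix_(idx, idx)])
            s12 = np.ascontiguousarray(Smat[idx, j])
            beta = B[idx, j].copy()
            beta = _lasso_cd(W11, s12, beta, alpha, inner_tol, inner_max_iter)
            B[idx, j] = beta
            w12 = W11 @ beta
            W[idx, j] = w12
            W[j, idx] = w12
            denom = W[j, j] - float(w12 @ beta)
            if denom <= 0:
                raise FloatingPointError("loss of positive definiteness in solver")
            theta_jj = 1.0 / denom
            theta[j, j] = theta_jj
            theta[idx, j] = -beta * theta_jj
            theta[j, idx] = -beta * theta_jj
        n_iter = sweep + 1
        history.append(penalized_loglik(theta, Smat, alpha, penalize_diagonal))
        gap = duality_gap(theta, Smat, alpha, penalize_diagonal)
        if abs(gap) < tol:
            converged = True
            break

    theta = (theta + theta.T) / 2.0
    W_out = np.linalg.inv(theta)
    W_out = (W_out + W_out.T) / 2.0
    return PrecisionEstimate(theta=theta, W=W_out, alpha=float(alpha), n_iter=n_iter,
                             gap=float(gap), converged=converged,
                             objective_history=history)


def _loglik_score(theta: np.ndarray, S_test: np.ndarray) -> float:
    """Held-out Gaussian log-likelihood (up to constants): logdet - tr(S theta)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return logdet - float(np.sum(S_test * theta))


def cross_validate_alpha(
    data: NormalizedMatrix | np.ndarray,
    n_folds: int = 5,
    n_refinements: int = 4,
    n_grid: int = 4,
    max_iter: int = 250,
    seed: int = 0,
    tol: float = 1e-4,
    alpha_min_ratio: float = 0.01,
    grid: list[float] | None = None,
) -> tuple[float, dict[float, float]]:
    """Pick the GLASSO penalty by K-fold cross-validated held-out likelihood.

    The grid starts log-spaced from alpha_max = max off-diagonal |S_ij| down
    to ``alpha_min_ratio * alpha_max`` and is refined ``n_refinements`` times
    around the running best; an explicit ``grid`` disables refinement and
    scores exactly those penalties. Returns the winning alpha and the full
    table of mean held-out log-likelihood per alpha evaluated. Deterministic
    for a fixed ``seed`` (folds are a seeded permutation split).
    """
    X = data.values if isinstance(data, NormalizedMatrix) else np.asarray(data, float)
    n = X.shape[0]
    if n_folds < 2 or n < n_folds:
        raise ValueError("need n_samples >= n_folds >= 2")
    if grid is None and n_grid < 2:
        raise ValueError("refinement needs n_grid >= 2; pass an explicit grid instead")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    for f in folds:
        if n - len(f) < 2:
            raise ValueError("a fold's training set has fewer than 2 samples")

    S_full = empirical_covariance(X).S
    off = np.abs(S_full - np.diag(np.diag(S_full)))
    alpha_max = max(off.max(), 1e-8)
    alpha_1, alpha_0 = alpha_max, alpha_max * alpha_min_ratio

    def _score_alpha(a: float) -> float:
        fold_scores = []
        for f in folds:
            train = np.setdiff1d(perm, f, assume_unique=False)
            S_train = empirical_covariance(X[train]).S
            if len(f) >= 2:
                S_test = empirical_covariance(X[f]).S
            else:
                xt = X[f] - X[train].mean(axis=0)
                S_test = xt.T @ xt / len(f)
            try:
                est = graphical_lasso(CovarianceEstimate(S_train, len(train)),
                                      alpha=a, tol=tol, max_iter=max_iter)
                fold_scores.append(_loglik_score(est.theta, S_test))
            except FloatingPointError:
                fold_scores.append(-np.inf)
        return float(np.mean(fold_scores))

    table: dict[float, float] = {}
    if grid is not None:
        if not grid:
            raise ValueError("grid must be non-empty")
        for a in grid:
            table[float(a)] = _score_alpha(float(a))
        alpha_best = max(table, key=table.get)
        return float(alpha_best), table

    for _ in range(n_refinements):
        alphas = np.logspace(np.log10(alpha_0), np.log10(alpha_1), n_grid)[::-1]
        scores = []
        for a in alphas:
            a = float(a)
            if a not in table:
                table[a] = _score_alpha(a)
            scores.append(table[a])
        best = int(np.argmax(scores))
        if best == 0:
            alpha_1 = alphas[0]
            alpha_0 = alphas[1]
        elif best == n_grid - 1:
            alpha_1 = alphas[best - 1]
            alpha_0 = alphas[best] * alpha_min_ratio
        else:
            alpha_1 = alphas[best - 1]
            alpha_0 = alphas[best + 1]
    alpha_best = max(table, key=table.get)
    return float(alpha_best), table


def network_from_precision(
    est: PrecisionEstimate,
    names: list[str],
    edge_threshold: float = 1e-8,
) -> SparseNetwork:
    """Convert a precision estimate into a partial-correlation network.

    An edge (i, j) exists iff |theta_ij| > edge_threshold; its weight is the
    partial correlation -theta_ij / sqrt(theta_ii * theta_jj). Metabolites
    left with no edges are dropped from the node list.
    """
    p = est.p
    if len(names) != p:
        raise ValueError(f"got {len(names)} names for a {p}x{p} precision matrix")
    P = est.partial_correlations()
    edges: list[tuple[str, str, float]] = []
    connected = np.zeros(p, dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(est.theta[i, j]) > edge_threshold:
                edges.append((names[i], names[j], float(P[i, j])))
                connected[i] = connected[j] = True
    nodes = [names[i] for i in range(p) if connected[i]]
    return SparseNetwork(nodes=nodes, edges=edges)
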