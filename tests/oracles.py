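"""Independent reference computations for tests.

The GLASSO oracle here is deliberately a different algorithm from the
package's blockwise coordinate-descent solver: proximal gradient ascent
(ISTA with backtracking and step growth) on the penalized log-likelihood

    log det(T) - tr(S T) - alpha * sum_{i != j} |T_ij|

run to a tight duality gap. Agreement between the two routes validates both.
"""
from __future__ import annotations

import numpy as np


def soft_threshold_offdiag(A: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(A) * np.maximum(np.abs(A) - t, 0.0)
    np.fill_diagonal(out, np.diag(A))
    return out


def _smooth_val(theta, S):
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    return -logdet + float(np.sum(S * theta))


def glasso_proximal_oracle(S: np.ndarray, alpha: float, tol: float = 1e-8,
                           max_iter: int = 100000) -> np.ndarray:
    """Proximal-gradient solution of the graphical lasso (off-diagonal penalty)."""
    S = np.asarray(S, float)
    p = S.shape[0]
    theta = np.linalg.inv(S + alpha * np.eye(p))
    theta = (theta + theta.T) / 2.0
    step = 1.0
    for _ in range(max_iter):
        inv_theta = np.linalg.inv(theta)
        grad = S - inv_theta  # gradient of the smooth part (to minimize)
        f0 = _smooth_val(theta, S)
        while True:
            cand = soft_threshold_offdiag(theta - step * grad, step * alpha)
            cand = (cand + cand.T) / 2.0
            diff = cand - theta
            f1 = _smooth_val(cand, S)
            if np.isfinite(f1) and f1 <= f0 + float(np.sum(grad * diff)) \
                    + float(np.sum(diff * diff)) / (2 * step) + 1e-15:
                break
            step *= 0.5
            if step < 1e-14:
                raise RuntimeError("oracle line search failed")
        theta = cand
        step *= 1.2
        off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
        gap = float(np.sum(S * theta)) - p + alpha * off
        if abs(gap) < tol:
            return theta
    raise RuntimeError("oracle did not converge")


def random_correlation_like(p: int, n: int, seed: int) -> np.ndarray:
    """Random PSD covariance of standardized data (unit diagonal)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X = X / sd
    return X.T @ X / n


def f1_edges(est: set[tuple[int, int]], true: set[tuple[int, int]]) -> float:
    tp = len(est & true)
    if tp == 0:
        return 0.0
    prec = tp / len(est)
    rec = tp / len(true)
    return 2 * prec * rec / (prec + rec)
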