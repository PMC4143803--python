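"""Fast gaussian elastic-net path with K-fold cross-validation.

Coordinate descent on the Gram matrix (suitable for the small per-gene
variant counts this package screens), jit-compiled with numba.  The
objective matches the usual penalized least squares

    (1/2n) ||y - X b||^2 + lambda [ alpha ||b||_1 + (1-alpha)/2 ||b||^2 ],

with the path run from lambda_max (all-zero solution) down over a
geometric grid and warm starts.  The unit tests cross-check coefficients
and the selected set against scikit-learn's coordinate descent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enet_cv_select", "enet_path_gram"]


@njit(cache=False, fastmath=False)
def _cd_path(G, b, n, lambdas, l1, max_sweeps, tol):
    p = G.shape[0]
    n_lam = lambdas.shape[0]
    coefs = np.zeros((p, n_lam))
    beta = np.zeros(p)
    for il in range(n_lam):
        lam = lambdas[il]
        thr = lam * l1 * n
        for _ in range(max_sweeps):
            max_delta = 0.0
            max_beta = 0.0
            for j in range(p):
                old = beta[j]
                # partial residual correlation, leaving coordinate j out
                z = b[j] - np.dot(G[j], beta) + G[j, j] * old
                if z > thr:
                    new = (z - thr) / (G[j, j] + lam * (1.0 - l1) * n)
                elif z < -thr:
                    new = (z + thr) / (G[j, j] + lam * (1.0 - l1) * n)
                else:
                    new = 0.0
                beta[j] = new
                d = abs(new - old)
                if d > max_delta:
                    max_delta = d
                if abs(new) > max_beta:
                    max_beta = abs(new)
            if max_delta <= tol * max(max_beta, 1e-12):
                break
        coefs[:, il] = beta
    return coefs


def enet_path_gram(X, y, lambdas, l1_ratio, max_sweeps: int = 1000, tol: float = 1e-6):
    """Coefficient path over a descending lambda grid (columns = lambdas)."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    G = X.T @ X
    b = X.T @ y
    return _cd_path(G, b, X.shape[0], np.asarray(lambdas, dtype=float),
                    float(l1_ratio), max_sweeps, tol)


def enet_cv_select(
    X, y, l1_ratio: float = 0.5, cv_folds: int = 10, seed: int = 0,
    n_lambdas: int = 100, eps: float = 1e-3, lambda_rule: str = "1se",
) -> np.ndarray:
    """Nonzero-coefficient indices at the cross-validated penalty.

    ``lambda_rule="min"`` takes the CV-error-minimizing lambda;
    ``"1se"`` (default) takes the largest lambda whose mean CV error is
    within one standard error of the minimum — the sparser, more
    conservative convention that keeps the selection empty for most genes
    with no signal.  Folds are contiguous blocks of a seeded permutation of
    the samples, so the same seed always reproduces the same selection.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, p = X.shape
    lam_max = np.abs(X.T @ y).max() / (n * l1_ratio)
    if lam_max <= 0:
        return np.empty(0, dtype=int)
    lambdas = np.geomspace(lam_max, lam_max * eps, n_lambdas)

    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.linspace(0, n, cv_folds + 1).astype(np.int64)
    fold_mse = np.zeros((cv_folds, n_lambdas))
    G = X.T @ X
    b = X.T @ y
    for f in range(cv_folds):
        te = perm[bounds[f]:bounds[f + 1]]
        Xte, yte = X[te], y[te]
        G_tr = G - Xte.T @ Xte
        b_tr = b - Xte.T @ yte
        coefs = _cd_path(G_tr, b_tr, n - te.size, lambdas, float(l1_ratio), 1000, 1e-6)
        resid = yte[:, None] - Xte @ coefs
        fold_mse[f] = np.mean(resid * resid, axis=0)
    mean_mse = fold_mse.mean(axis=0)
    i_min = int(np.argmin(mean_mse))
    if lambda_rule == "1se":
        se_min = float(fold_mse[:, i_min].std(ddof=1) / np.sqrt(cv_folds))
        # lambdas are descending; take the largest within one SE of the best
        best = int(np.argmax(mean_mse <= mean_mse[i_min] + se_min))
    else:
        best = i_min
    coefs = _cd_path(G, b, n, lambdas[: best + 1], float(l1_ratio), 1000, 1e-6)
    return np.flatnonzero(np.abs(coefs[:, best]) > 1e-10)
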