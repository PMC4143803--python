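"""The two-step rPLS gene-based association test.

Step 1 screens the gene's SNVs with an elastic net (covariates unpenalized),
keeping the variants with nonzero coefficients at the cross-validated
penalty.  Step 2 collapses the selected dosage columns into a single
"supervariant" t = Xs w, where w is the first partial-least-squares loading
w = Xs' y / ||Xs' y|| (columns and working response centered), and tests
H0: beta* = 0 in the GLM  g(mu) = b0 + t beta* + Z gamma.

The screening and the test use the same data, so the per-gene p-value is
not selection-corrected; under a global null the test is anticonservative,
increasingly so as the causal fraction of the gene grows.  The magnitudes
|w_j| rank the selected SNVs by their contribution to the supervariant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._glm import add_intercept, fit_null, wald_1df

logger = logging.getLogger("rplskit")

__all__ = [
    "RplsConfig",
    "RplsFit",
    "DegeneratePLSError",
    "elastic_net_screen",
    "pls_supervariant",
    "glm_test_supervariant",
    "rpls_test",
    "rank_snvs",
]


class DegeneratePLSError(ValueError):
    """Working response orthogonal to every selected column."""


@dataclass(frozen=True)
class RplsConfig:
    """Tunable parameters of the rPLS procedure.

    en_alpha is the elastic-net mixing weight on the L1 term (1 = lasso);
    the penalty strength is chosen by ``cv_folds``-fold cross-validation
    with fold assignment seeded by ``seed``.
    """

    en_alpha: float = 0.5
    cv_folds: int = 10
    seed: int = 0
    family: str = "gaussian"
    n_lambdas: int = 100
    lambda_rule: str = "1se"

    def __post_init__(self):
        if not 0.0 < self.en_alpha <= 1.0:
            raise ValueError("en_alpha must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class RplsFit:
    """Fitted rPLS result for one gene."""

    selected_idx: np.ndarray           # indices into the gene's columns
    loading_w: np.ndarray              # unit first-PLS loading, length k
    supervariant_t: np.ndarray | None  # length-n scores (None when k = 0)
    beta_star: float
    beta0: float
    gamma: np.ndarray
    p_value: float
    snv_ranking: list                  # variant ids by non-increasing |w|
    statistic: float = 0.0
    flags: list[str] = field(default_factory=list)
    variant_ids: list = field(default_factory=list)
    positions: np.ndarray | None = None

    @property
    def k(self) -> int:
        return int(self.selected_idx.size)


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; zero-variance columns are left centered only."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = X - mu
    Xs[:, ok] /= sd[ok]
    return Xs, ok


def elastic_net_screen(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    family: str = "gaussian",
    mixing: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_rule: str = "1se",
) -> np.ndarray:
    """Indices of SNVs with nonzero elastic-net coefficients at the CV penalty.

    Dosage columns are standardized internally; covariates are never
    penalized.  For the gaussian family the covariates are profiled out
    exactly (residualizing y and X on [1, Z] leaves the penalized solution
    unchanged); for the binomial family the covariate coefficients carry a
    zero penalty weight in a logistic elastic net, with the penalty strength
    chosen on a deviance-CV grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"elastic-net screening needs n >= 10, got {n}")
    if y.shape[0] != n:
        raise ValueError("X and y have different sample counts")
    if cv_folds > n:
        raise ValueError("more CV folds than samples")

    Xs, ok = _standardize_columns(X)
    if not np.any(ok):
        return np.empty(0, dtype=int)

    if family == "gaussian":
        sel = _en_screen_gaussian(
            Xs[:, ok], y, Z, mixing, cv_folds, seed, n_lambdas, lambda_rule
        )
    elif family == "binomial":
        sel = _en_screen_binomial(
            Xs[:, ok], y, Z, mixing, cv_folds, seed, n_lambdas, lambda_rule
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    return np.flatnonzero(ok)[sel]


def _en_screen_gaussian(Xs, y, Z, mixing, cv_folds, seed, n_lambdas, lambda_rule):
    from ._enet import enet_cv_select

    n = Xs.shape[0]
    X0 = add_intercept(Z, n)
    # profile out the unpenalized block (Frisch-Waugh for penalized fits)
    H, *_ = np.linalg.lstsq(X0, np.hstack([y[:, None], Xs]), rcond=None)
    fitted = X0 @ H
    y_r = y - fitted[:, 0]
    X_r = Xs - fitted[:, 1:]
    return enet_cv_select(
        X_r, y_r, l1_ratio=mixing, cv_folds=cv_folds, seed=seed,
        n_lambdas=n_lambdas, lambda_rule=lambda_rule,
    )


def _en_screen_binomial(Xs, y, Z, mixing, cv_folds, seed, n_lambdas, lambda_rule):
    import statsmodels.api as sm
    from sklearn.model_selection import StratifiedKFold

    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial trait must take values in {0, 1}")
    n, p = Xs.shape
    X0 = add_intercept(Z, n)
    design = np.hstack([X0, Xs])
    pen = np.r_[np.zeros(X0.shape[1]), np.ones(p)]

    null = fit_null(y, Z, "binomial")
    lam_max = np.abs(Xs.T @ null.resid).max() / (n * mixing)
    n_grid = min(n_lambdas, 25)
    lambdas = np.geomspace(lam_max * 1.05, lam_max * 0.01, n_grid)

    def _fit(Xd, yd, lam):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(yd, Xd, family=sm.families.Binomial()).fit_regularized(
                method="elastic_net", alpha=lam * pen, L1_wt=mixing, maxiter=200
            )

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_dev = np.zeros((cv_folds, n_grid))
    for f, (train, test) in enumerate(cv.split(design, y)):
        for i, lam in enumerate(lambdas):
            try:
                res = _fit(design[train], y[train], lam)
            except Exception:
                fold_dev[f, i] = np.inf
                logger.warning("elastic-net fit failed at lambda=%.3g; skipped", lam)
                continue
            eta = design[test] @ res.params
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
            fold_dev[f, i] = -2.0 * np.mean(
                y[test] * np.log(mu) + (1 - y[test]) * np.log1p(-mu)
            )
    mean_dev = fold_dev.mean(axis=0)
    if not np.any(np.isfinite(mean_dev)):
        raise RuntimeError("elastic net failed to converge at every lambda")
    i_min = int(np.nanargmin(np.where(np.isfinite(mean_dev), mean_dev, np.nan)))
    if lambda_rule == "1se":
        se_min = float(fold_dev[:, i_min].std(ddof=1) / np.sqrt(cv_folds))
        best_i = int(np.argmax(mean_dev <= mean_dev[i_min] + se_min))
    else:
        best_i = i_min
    best = _fit(design, y, lambdas[best_i])
    return np.flatnonzero(np.abs(np.asarray(best.params)[X0.shape[1]:]) > 1e-10)


def pls_supervariant(Xs: np.ndarray, y_work: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First PLS loading and scores for the selected dosage columns.

    With centered inputs the first PLS component (NIPALS and SIMPLS agree
    for one component) is  w = Xs' y / ||Xs' y||,  t = Xs w.  Inputs are
    centered here, so passing already-centered arrays is harmless.
    """
    Xs = np.asarray(Xs, dtype=float)
    if Xs.ndim == 1:
        Xs = Xs[:, None]
    y_work = np.asarray(y_work, dtype=float).ravel()
    if Xs.shape[0] != y_work.shape[0]:
        raise ValueError("Xs and y_work have different sample counts")
    if Xs.shape[1] < 1:
        raise ValueError("need at least one selected column")
    Xc = Xs - Xs.mean(axis=0)
    yc = y_work - y_work.mean()
    c = Xc.T @ yc
    norm = np.linalg.norm(c)
    if norm <= 1e-12 * max(1.0, np.abs(Xc).max() * np.abs(yc).max()):
        raise DegeneratePLSError("working response orthogonal to selected columns")
    w = c / norm
    return w, Xc @ w


def glm_test_supervariant(
    t: np.ndarray,
    Z: np.ndarray | None,
    y: np.ndarray,
    family: str = "gaussian",
):
    """Wald test of the supervariant slope beta* in g(mu)=b0+t*beta*+Z*gamma.

    Returns (beta_star, p_value, details) where details carries the test
    statistic, intercept, covariate coefficients and any degeneracy flags.
    """
    beta_star, stat, p, coefs, flags = wald_1df(t, Z, y, family)
    details = {
        "statistic": stat,
        "beta0": float(coefs[0]) if coefs.size else 0.0,
        "gamma": np.asarray(coefs[2:]) if coefs.size > 2 else np.empty(0),
        "flags": flags,
    }
    return beta_star, p, details


def rpls_test(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    family: str = "gaussian",
    config: RplsConfig | None = None,
    variant_ids=None,
    positions=None,
) -> RplsFit:
    """Run the full two-step rPLS test on one gene.

    Genes where the elastic net selects nothing, or where the PLS step is
    degenerate, return p_value = 1 with an empty ranking so genome-wide
    summaries stay well defined.
    """
    from .estimators import RPLSTest

    config = config or RplsConfig(family=family)
    if config.family != family:
        config = RplsConfig(
            en_alpha=config.en_alpha,
            cv_folds=config.cv_folds,
            seed=config.seed,
            family=family,
            n_lambdas=config.n_lambdas,
            lambda_rule=config.lambda_rule,
        )
    est = RPLSTest(
        en_alpha=config.en_alpha,
        cv_folds=config.cv_folds,
        seed=config.seed,
        family=config.family,
        n_lambdas=config.n_lambdas,
        lambda_rule=config.lambda_rule,
    )
    est.fit(X, y, Z=Z, variant_ids=variant_ids, positions=positions)
    return est.fit_result_


def rank_snvs(fit: RplsFit) -> list:
    """Selected variant ids by non-increasing |loading|, position-tiebroken."""
    if fit.k == 0:
        return []
    sel = fit.selected_idx
    pos = (
        fit.positions[sel]
        if fit.positions is not None
        else np.asarray(sel, dtype=float)
    )
    order = np.lexsort((pos, -np.abs(fit.loading_w)))
    ids = fit.variant_ids if fit.variant_ids else list(range(int(np.max(sel)) + 1))
    return [ids[sel[i]] for i in order]
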