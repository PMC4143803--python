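"""Small GLM helpers: null-model fits and 1-df Wald tests.

Gaussian-family Wald tests use the exact t reference (classical OLS
inference); binomial-family tests use the asymptotic normal reference from
the logistic IRLS fit, which is standard for logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NullModel", "fit_null", "wald_1df", "add_intercept"]

FAMILIES = ("gaussian", "binomial")


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")


def add_intercept(Z: np.ndarray | None, n: int) -> np.ndarray:
    """Design matrix [1, Z] (just the intercept when Z is None/empty)."""
    one = np.ones((n, 1))
    if Z is None or Z.size == 0:
        return one
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("covariate rows do not match sample count")
    return np.hstack([one, Z])


@dataclass
class NullModel:
    """Covariates-only GLM fit g(mu) = b0 + Z gamma."""

    family: str
    X0: np.ndarray          # (n, q0) design incl. intercept
    mu: np.ndarray          # fitted means
    resid: np.ndarray       # y - mu
    sigma2: float           # residual variance (RSS / (n - q0)); 1.0 for binomial
    irls_w: np.ndarray      # IRLS weights: 1 for gaussian, mu(1-mu) for binomial

    @property
    def df_resid(self) -> int:
        return self.X0.shape[0] - self.X0.shape[1]


def fit_null(y: np.ndarray, Z: np.ndarray | None, family: str) -> NullModel:
    """Fit the covariates-only null model."""
    _check_family(family)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X0 = add_intercept(Z, n)
    if family == "gaussian":
        beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
        mu = X0 @ beta
        resid = y - mu
        dof = n - X0.shape[1]
        if dof <= 0:
            raise ValueError("null model has no residual degrees of freedom")
        return NullModel(family, X0, mu, resid, float(resid @ resid / dof), np.ones(n))
    _check_binary(y)
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X0, family=sm.families.Binomial()).fit(maxiter=100)
    mu = np.asarray(fit.mu)
    if not fit.converged:
        raise RuntimeError("binomial null model failed to converge")
    return NullModel(family, X0, mu, y - mu, 1.0, mu * (1.0 - mu))


def _check_binary(y: np.ndarray) -> None:
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial trait must take values in {0, 1}")
    if y.min() == y.max():
        raise ValueError("binomial trait is constant")


def wald_1df(
    t: np.ndarray,
    Z: np.ndarray | None,
    y: np.ndarray,
    family: str,
) -> tuple[float, float, float, np.ndarray, list[str]]:
    """Two-sided Wald test of the supervariant slope in g(mu)=b0+t*b+Z*gamma.

    Returns (beta, statistic, p_value, all_coefs, flags).  The gaussian case
    is the exact OLS t-test; the binomial case is the logistic z-test, with
    perfect separation mapped to p = 1 and a flag.
    """
    _check_family(family)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    n = y.shape[0]
    if t.shape[0] != n:
        raise ValueError("supervariant length does not match trait length")
    if np.ptp(t) == 0:
        return 0.0, 0.0, 1.0, np.zeros(1), ["constant_supervariant"]
    X0 = add_intercept(Z, n)
    X = np.hstack([X0[:, :1], t[:, None], X0[:, 1:]])  # [1, t, Z]

    if family == "gaussian":
        dof = n - X.shape[1]
        if dof <= 0:
            raise ValueError("design has no residual degrees of freedom")
        xtx = X.T @ X
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design in supervariant GLM") from exc
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        s2 = float(resid @ resid) / dof
        se = np.sqrt(s2 * xtx_inv[1, 1])
        tstat = beta[1] / se
        p = 2.0 * stats.t.sf(abs(tstat), dof)
        return float(beta[1]), float(tstat), float(p), beta, []

    _check_binary(y)
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return 0.0, 0.0, 1.0, np.zeros(X.shape[1]), ["perfect_separation"]
    beta = np.asarray(fit.params)
    se = np.asarray(fit.bse)
    # IRLS walks off to infinity under (quasi-)separation: huge coefs/SEs
    if not fit.converged or not np.isfinite(se[1]) or se[1] > 1e3 or abs(beta[1]) > 1e2:
        return 0.0, 0.0, 1.0, beta, ["perfect_separation"]
    z = beta[1] / se[1]
    p = 2.0 * stats.norm.sf(abs(z))
    return float(beta[1]), float(z), float(p), beta, []
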