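"""Functional wrappers for the comparison tests (SUM, SKAT, SKAT-O).

Each wrapper fits the corresponding estimator from
:mod:`rplskit.estimators` on one gene and returns a
:class:`rplskit.results.GeneTestResult` row.
"""

from __future__ import annotations

import numpy as np

from .estimators import DEFAULT_RHO_GRID, SKATOTest, SKATTest, SumTest
from .results import GeneTestResult

__all__ = ["sum_test", "skat_test", "skat_o_test"]


def sum_test(X, y, Z=None, family: str = "gaussian", gene: str = "") -> GeneTestResult:
    """1-df burden test on the per-sample minor-allele count."""
    est = SumTest(family=family).fit(X, y, Z=Z)
    return GeneTestResult(
        gene=gene,
        method="SUM",
        p_value=est.p_value_,
        statistic=est.statistic_,
        df_or_params={"df": 1, "beta": est.beta_},
        flags=list(est.flags_),
    )


def skat_test(
    X, y, Z=None, family: str = "gaussian",
    weights_beta=(1.0, 25.0), flat_weights: bool = False,
    maf=None, gene: str = "",
) -> GeneTestResult:
    """SKAT variance-component test with Beta-density MAF weights."""
    est = SKATTest(family=family, weights_beta=weights_beta,
                   flat_weights=flat_weights).fit(X, y, Z=Z, maf=maf)
    return GeneTestResult(
        gene=gene,
        method="SKAT",
        p_value=est.p_value_,
        statistic=est.statistic_,
        df_or_params={"n_lambda": int(np.size(est.lambdas_))},
        flags=list(est.flags_),
    )


def skat_o_test(
    X, y, Z=None, family: str = "gaussian",
    weights_beta=(1.0, 25.0), flat_weights: bool = False,
    rho_grid=DEFAULT_RHO_GRID, maf=None, gene: str = "",
) -> GeneTestResult:
    """SKAT-O: optimal SKAT/burden combination over the rho grid."""
    est = SKATOTest(family=family, weights_beta=weights_beta,
                    flat_weights=flat_weights, rho_grid=rho_grid).fit(X, y, Z=Z, maf=maf)
    return GeneTestResult(
        gene=gene,
        method="SKAT-O",
        p_value=est.p_value_,
        statistic=est.statistic_,
        df_or_params={"rho_opt": est.rho_opt_},
        flags=list(est.flags_),
    )
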