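"""Analysis traits derived from blood-pressure measurements.

Four traits are supported: the raw quantitative traits SBP and DBP (mm Hg),
the binary hypertension status HTN (pressure thresholds or medication use),
and PC1, the leading principal component of standardized SBP and DBP, which
pools the two pressure signals into one quantitative composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TraitSpec", "derive_htn", "derive_pc1"]

_FAMILIES = {"DBP": "gaussian", "SBP": "gaussian", "PC1": "gaussian", "HTN": "binomial"}


@dataclass(frozen=True)
class TraitSpec:
    """A named analysis trait and its GLM family."""

    name: str
    family: str

    def __post_init__(self):
        if self.name in _FAMILIES and self.family != _FAMILIES[self.name]:
            raise ValueError(
                f"trait {self.name} must have family {_FAMILIES[self.name]!r}"
            )

    @classmethod
    def from_name(cls, name: str) -> "TraitSpec":
        if name not in _FAMILIES:
            raise ValueError(f"unknown trait {name!r}; choose from {sorted(_FAMILIES)}")
        return cls(name=name, family=_FAMILIES[name])


def derive_htn(sbp, dbp, on_medication):
    """Hypertension case status: SBP >= 140 mm Hg, DBP >= 90 mm Hg, or medicated.

    Inputs may be scalars or arrays; thresholds are inclusive.  A missing
    medication flag yields a missing (nan) status so the row can be dropped
    downstream.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(on_medication, dtype=float)
    if np.any(sbp[np.isfinite(sbp)] < 0) or np.any(dbp[np.isfinite(dbp)] < 0):
        raise ValueError("blood pressures must be non-negative")
    status = ((sbp >= 140) | (dbp >= 90) | (med == 1)).astype(float)
    status = np.where(np.isfinite(med), status, np.nan)
    if status.ndim == 0:
        return float(status)
    return status


def derive_pc1(sbp_vec, dbp_vec):
    """Scores on the first principal component of standardized (SBP, DBP).

    Both columns are standardized to mean 0 / sd 1 (ddof=1), so the 2x2
    covariance matrix is the correlation matrix and the result is invariant
    to affine rescaling of either input.  The loading on SBP is fixed
    positive, so larger PC1 means higher blood pressure.  Scores have mean 0.

    For a 2x2 correlation matrix with correlation r, the leading eigenvector
    is (1, sign(r))/sqrt(2) with eigenvalue 1 + |r|, so the scores are
    (z_sbp + sign(r) z_dbp)/sqrt(2) -- with the SBP-positive sign convention.
    """
    sbp = np.asarray(sbp_vec, dtype=float)
    dbp = np.asarray(dbp_vec, dtype=float)
    if sbp.shape != dbp.shape or sbp.ndim != 1:
        raise ValueError("sbp_vec and dbp_vec must be 1-d arrays of equal length")
    if sbp.size < 3:
        raise ValueError("need at least 3 samples for PC1")
    sds = sbp.std(ddof=1), dbp.std(ddof=1)
    if sds[0] == 0 or sds[1] == 0:
        raise ValueError("constant SBP or DBP column; PC1 undefined")
    z = np.column_stack([(sbp - sbp.mean()) / sds[0], (dbp - dbp.mean()) / sds[1]])
    r = float(np.corrcoef(z, rowvar=False)[0, 1])
    # closed-form leading eigenvector of [[1, r], [r, 1]]; for r = 0 every
    # direction is an eigenvector and we take the equal-weight composite
    s = 1.0 if r >= 0 else -1.0
    lead = np.array([1.0, s]) / np.sqrt(2.0)
    return z @ lead
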