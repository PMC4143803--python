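"""Power, type-I-error and accuracy summaries over replicate designs.

Definitions follow the replicate-design conventions:

* power of a causal gene = fraction of replicates in which it is declared
  significant at the nominal alpha;
* type I error = (total false positives) / (number of noncausal genes x
  number of replicates);
* accuracy of one replicate = (TP + TN) / (TP + TN + FP + FN) over the
  per-gene decisions.

A gene is "detected" iff p <= alpha; raw per-gene p-values are thresholded
at the nominal level with no multiple-testing correction (an optional
Bonferroni flag exists but defaults to off).  Method failures are recorded
as p = 1 (non-detections), never as dropped genes, so denominators always
match the formulas above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import RPLSTest, SKATOTest, SKATTest, SumTest
from .results import GeneTestResult
from .simulate import ReplicateSet

logger = logging.getLogger("rplskit")

__all__ = [
    "EvaluationSummary",
    "power_single_gene",
    "type1_across_genes",
    "accuracy_single_replicate",
    "make_estimator",
    "run_gene_tests",
    "run_benchmark",
    "summary_frame",
    "results_frame",
]

METHOD_NAMES = {"rpls": "rPLS", "sum": "SUM", "skat": "SKAT", "skato": "SKAT-O"}


@dataclass
class EvaluationSummary:
    """Aggregated decisions for one method on one trait."""

    method: str
    trait: str
    alpha: float
    power: float
    type1: float
    accuracy: float
    per_gene_counts: dict = field(default_factory=dict)
    n_replicates: int = 0

    def __post_init__(self):
        for name, v in (("power", self.power), ("type1", self.type1),
                        ("accuracy", self.accuracy)):
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")


def power_single_gene(detections: int, n_replicates: int) -> float:
    """Fraction of replicates in which the gene was detected."""
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    if not 0 <= detections <= n_replicates:
        raise ValueError("detections must lie in [0, n_replicates]")
    return detections / n_replicates


def type1_across_genes(false_positives_total: int, n_noncausal: int,
                       n_replicates: int) -> float:
    """Total false positives over (noncausal genes x replicates)."""
    if min(false_positives_total, n_noncausal, n_replicates) < 0:
        raise ValueError("counts must be non-negative")
    denom = n_noncausal * n_replicates
    if denom == 0:
        raise ValueError("zero noncausal-gene x replicate denominator")
    return false_positives_total / denom


def accuracy_single_replicate(tp: int, fn: int, fp: int, tn: int) -> float:
    """(TP + TN) / all gene decisions in one replicate."""
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("no gene decisions")
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")
    return (tp + tn) / total


def make_estimator(method: str, family: str, alpha_en: float = 0.5,
                   cv_folds: int = 10, seed: int = 0, flat_weights: bool = False,
                   weights_beta=(1.0, 25.0), rho_grid=None):
    """Construct a per-gene test estimator by short method name."""
    m = method.lower().replace("-", "")
    if m == "rpls":
        return RPLSTest(en_alpha=alpha_en, cv_folds=cv_folds, seed=seed, family=family)
    if m == "sum":
        return SumTest(family=family)
    if m == "skat":
        return SKATTest(family=family, weights_beta=weights_beta,
                        flat_weights=flat_weights)
    if m == "skato":
        kw = {} if rho_grid is None else {"rho_grid": rho_grid}
        return SKATOTest(family=family, weights_beta=weights_beta,
                         flat_weights=flat_weights, **kw)
    raise ValueError(f"unknown method {method!r}")


def run_gene_tests(G, gene_map, y, Z, family, methods, seed: int = 0,
                   maf_max: float | None = None, **est_kw) -> list[GeneTestResult]:
    """Run each requested method on each gene; failures become p = 1 rows."""
    out: list[GeneTestResult] = []
    for gene, idx in gene_map:
        if maf_max is not None and G.maf is not None:
            idx = idx[G.maf[idx] <= maf_max]
        X = G.dosages[:, idx]
        maf = None if G.maf is None else G.maf[idx]
        for method in methods:
            name = METHOD_NAMES[method.lower().replace("-", "")]
            if X.shape[1] == 0:
                out.append(GeneTestResult(gene, name, 1.0, flags=["no_variants"]))
                continue
            est = make_estimator(method, family=family, seed=seed, **est_kw)
            try:
                if isinstance(est, (SKATTest, SKATOTest)):
                    est.fit(X, y, Z=Z, maf=maf)
                elif isinstance(est, RPLSTest):
                    est.fit(X, y, Z=Z,
                            variant_ids=[G.variant_ids[i] for i in idx],
                            positions=G.positions[idx])
                else:
                    est.fit(X, y, Z=Z)
            except Exception as exc:
                logger.warning("%s failed on gene %s: %s", name, gene, exc)
                out.append(GeneTestResult(gene, name, 1.0, flags=["method_error"]))
                continue
            extra = {}
            if isinstance(est, RPLSTest):
                extra = {"k": est.fit_result_.k,
                         "top_snv": est.snv_ranking_[0] if est.snv_ranking_ else ""}
            elif isinstance(est, SKATOTest):
                extra = {"rho_opt": est.rho_opt_}
            out.append(GeneTestResult(gene, name, est.p_value_,
                                      statistic=getattr(est, "statistic_", None),
                                      df_or_params=extra,
                                      flags=list(est.flags_)))
    return out


def run_benchmark(replicates: ReplicateSet, methods, alpha: float = 0.001,
                  trait: str = "sim", seed: int = 0, bonferroni: bool = False,
                  **est_kw) -> list[EvaluationSummary]:
    """Full benchmark: per-gene decisions over every replicate, aggregated.

    Returns one :class:`EvaluationSummary` per method.  ``bonferroni``
    divides alpha by the number of genes before thresholding (off by
    default, matching the raw-nominal-threshold convention).
    """
    truth = replicates.truth
    genes = list(replicates.gene_map.genes)
    causal = [g for g in genes if truth.get(g, False)]
    noncausal = [g for g in genes if not truth.get(g, False)]
    thr = alpha / len(genes) if bonferroni else alpha
    R = replicates.n_replicates

    summaries = []
    for method in methods:
        name = METHOD_NAMES[method.lower().replace("-", "")]
        counts = {g: 0 for g in genes}
        acc = np.zeros(R)
        for r in range(R):
            res = run_gene_tests(
                replicates.genotype, replicates.gene_map,
                replicates.phenotypes[r], replicates.covariates,
                replicates.family, [method], seed=seed, **est_kw,
            )
            detected = {row.gene for row in res if row.p_value <= thr}
            for g in detected:
                counts[g] += 1
            tp = sum(g in detected for g in causal)
            fp = sum(g in detected for g in noncausal)
            acc[r] = accuracy_single_replicate(
                tp, len(causal) - tp, fp, len(noncausal) - fp
            )
        power = (
            float(np.mean([power_single_gene(counts[g], R) for g in causal]))
            if causal else float("nan")
        )
        type1 = (
            type1_across_genes(sum(counts[g] for g in noncausal), len(noncausal), R)
            if noncausal else float("nan")
        )
        summaries.append(EvaluationSummary(
            method=name, trait=trait, alpha=alpha, power=power, type1=type1,
            accuracy=float(acc.mean()), per_gene_counts=counts, n_replicates=R,
        ))
    return summaries


def summary_frame(summaries) -> pd.DataFrame:
    """Tidy one-row-per-(method, trait) table of the aggregate rates."""
    return pd.DataFrame(
        [
            {
                "method": s.method,
                "trait": s.trait,
                "alpha": s.alpha,
                "power": s.power,
                "type1": s.type1,
                "accuracy": s.accuracy,
                "n_replicates": s.n_replicates,
            }
            for s in summaries
        ]
    )


def results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """Tidy per-gene result rows: gene, method, p_value, k, top_snv, flags."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "method": r.method,
                "p_value": r.p_value,
                "statistic": r.statistic,
                "k": r.df_or_params.get("k", ""),
                "top_snv": r.df_or_params.get("top_snv", ""),
                "rho_opt": r.df_or_params.get("rho_opt", ""),
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
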