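"""Synthetic genotype/phenotype generator with a replicate design.

The generator emulates a replicate-based evaluation design: genotypes are
drawn once and held fixed, while the phenotype is
re-simulated many times (replicates) from a known generating model, so that
per-gene power is a fraction of replicates.  Features emulated:

* a rare-skewed MAF spectrum, maf ~ min(Beta(0.2, 5), 0.5);
* genes containing mixtures of causal and noncausal SNVs, with effect
  directions that may differ within one gene;
* quantitative traits linear in dosage plus age and sex covariates;
* a binary trait via a liability threshold at a configured prevalence, and
  a blood-pressure-style pair (SBP, DBP) from which hypertension status can
  be derived;
* optional within-gene LD through a latent AR(1) gaussian copula.

All randomness flows from ``SimulationConfig.seed`` through named
substreams (genotypes / covariates / phenotypes), so a config reproduces a
ReplicateSet bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

from .io import GeneMap, GenotypeMatrix
from .phenotypes import derive_htn

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "ReplicateSet",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_bp_replicates",
    "gene_map_from_config",
    "gene_intervals",
    "default_scenario",
    "small_scenario",
    "load_scenario",
    "save_scenario",
]

_GENE_SPACING = 1_000_000  # bp between gene blocks on the synthetic chromosome


@dataclass(frozen=True)
class GeneSpec:
    """One gene: SNV count and the signed effects of its causal SNVs.

    ``causal_maf`` optionally pins the population MAF of each causal SNV
    (instead of drawing it from the scenario's spectrum), e.g. to model a
    well-typed moderate-frequency driver variant.
    """

    name: str
    n_snvs: int
    causal_idx: tuple = ()
    effect_sizes: tuple = ()
    causal_maf: tuple = ()

    def __post_init__(self):
        if len(self.causal_idx) != len(self.effect_sizes):
            raise ValueError(f"{self.name}: causal_idx and effect_sizes differ in length")
        if any(not 0 <= i < self.n_snvs for i in self.causal_idx):
            raise ValueError(f"{self.name}: causal_idx out of range")
        if self.causal_maf and len(self.causal_maf) != len(self.causal_idx):
            raise ValueError(f"{self.name}: causal_maf length mismatch")

    @property
    def is_causal(self) -> bool:
        return len(self.causal_idx) > 0


@dataclass
class SimulationConfig:
    """Scenario parameters; defaults mirror a small unrelated-individuals cohort.

    ``n_samples`` defaults to 150 (a cohort on the scale of the ~140
    unrelated individuals typical of this design); ``n_replicates`` defaults
    to the 200-replicate convention.  ``covariate_effects`` are the (age,
    sex) slopes on the quantitative-trait scale.
    """

    genes: list = field(default_factory=list)
    n_samples: int = 150
    n_replicates: int = 200
    maf_beta: tuple = (0.2, 5.0)
    maf_max: float = 0.5
    noise_sd: float = 1.0
    beta0: float = 0.0
    covariate_effects: tuple = (0.01, 0.25)
    trait_model: str = "gaussian"  # gaussian | liability
    prevalence: float = 0.3
    ld_rho: float = 0.0
    ensure_polymorphic: bool = True
    seed: int = 0

    def __post_init__(self):
        self.genes = [g if isinstance(g, GeneSpec) else GeneSpec(**g) for g in self.genes]
        if self.trait_model not in ("gaussian", "liability"):
            raise ValueError("trait_model must be 'gaussian' or 'liability'")

    @property
    def truth(self) -> dict:
        return {g.name: g.is_causal for g in self.genes}


@dataclass
class ReplicateSet:
    """Fixed genotypes/covariates plus an (n_replicates, n) phenotype matrix."""

    genotype: GenotypeMatrix
    covariates: np.ndarray        # (n, 2): age, sex
    covariate_names: list
    phenotypes: np.ndarray        # (n_replicates, n)
    family: str
    truth: dict
    gene_map: GeneMap
    config: SimulationConfig

    @property
    def n_replicates(self) -> int:
        return self.phenotypes.shape[0]


def _streams(seed: int):
    g, c, p = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(g),
        np.random.default_rng(c),
        np.random.default_rng(p),
    )


def _draw_gene_dosages(rng, n: int, cfg: SimulationConfig, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Dosage block and its population MAFs for one gene."""
    a, b = cfg.maf_beta
    maf = np.minimum(rng.beta(a, b, size=p), cfg.maf_max)
    if cfg.ld_rho > 0:
        # latent AR(1) gaussian copula across the gene's variants
        e = rng.standard_normal((n, p))
        z = np.empty_like(e)
        z[:, 0] = e[:, 0]
        r = cfg.ld_rho
        for j in range(1, p):
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * e[:, j]
        u = stats.norm.cdf(z)
        d = stats.binom.ppf(u, 2, maf)
        return d.astype(float), maf
    d = rng.binomial(2, maf, size=(n, p)).astype(float)
    if cfg.ensure_polymorphic:
        for j in range(p):
            tries = 0
            while np.ptp(d[:, j]) == 0:
                maf[j] = min(rng.beta(a, b), cfg.maf_max)
                d[:, j] = rng.binomial(2, maf[j], size=n)
                tries += 1
                if tries > 1000:  # pragma: no cover
                    raise RuntimeError("could not draw a polymorphic variant")
    return d, maf


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw the fixed genotype matrix for all genes in the scenario.

    Dosages are Binomial(2, maf) per variant under HWE, independent across
    variants unless ``ld_rho`` > 0.  Genes occupy disjoint position blocks
    on a single synthetic chromosome, so interval-based gene mapping works
    end to end.
    """
    rng, _, _ = _streams(config.seed)
    blocks, mafs, vids, positions = [], [], [], []
    for gi, gene in enumerate(config.genes):
        d, maf = _draw_gene_dosages(rng, config.n_samples, config, gene.n_snvs)
        if gene.causal_maf:
            # pinned-MAF causal SNVs are redrawn independently (outside any
            # LD copula) at their stated frequency
            for local_j, m in zip(gene.causal_idx, gene.causal_maf):
                maf[local_j] = m
                col = rng.binomial(2, m, size=config.n_samples).astype(float)
                while config.ensure_polymorphic and np.ptp(col) == 0:
                    col = rng.binomial(2, m, size=config.n_samples).astype(float)
                d[:, local_j] = col
        blocks.append(d)
        mafs.append(maf)
        base = gi * _GENE_SPACING
        vids.extend(f"{gene.name}_snv{j}" for j in range(gene.n_snvs))
        positions.extend(base + 1 + j for j in range(gene.n_snvs))
    if not blocks:
        raise ValueError("scenario has no genes")
    dos = np.hstack(blocks)
    p = dos.shape[1]
    return GenotypeMatrix(
        dosages=dos,
        sample_ids=[f"S{i:04d}" for i in range(config.n_samples)],
        variant_ids=vids,
        chrom=np.asarray(["1"] * p, dtype=object),
        positions=np.asarray(positions, dtype=int),
        ref=np.asarray(["A"] * p, dtype=object),
        alt=np.asarray(["C"] * p, dtype=object),
        maf=np.concatenate(mafs),
    )


def gene_map_from_config(config: SimulationConfig) -> GeneMap:
    """GeneMap matching the column layout of :func:`simulate_genotypes`."""
    genes, start = {}, 0
    for g in config.genes:
        genes[g.name] = np.arange(start, start + g.n_snvs)
        start += g.n_snvs
    return GeneMap(genes=genes)


def gene_intervals(config: SimulationConfig, convention: str = "bed") -> list:
    """(gene, chrom, start, end) intervals matching the synthetic positions."""
    out = []
    for gi, g in enumerate(config.genes):
        base = gi * _GENE_SPACING
        if convention == "bed":
            out.append((g.name, "1", base, base + g.n_snvs))
        else:
            out.append((g.name, "1", base + 1, base + g.n_snvs))
    return out


def _draw_covariates(config: SimulationConfig) -> np.ndarray:
    _, rng, _ = _streams(config.seed)
    age = rng.uniform(20.0, 80.0, size=config.n_samples)
    sex = rng.binomial(1, 0.5, size=config.n_samples).astype(float)
    return np.column_stack([age, sex])


def _genetic_predictor(G: GenotypeMatrix, config: SimulationConfig) -> np.ndarray:
    gmap = gene_map_from_config(config)
    eta = np.zeros(config.n_samples)
    for g in config.genes:
        idx = gmap[g.name]
        for local_j, beta in zip(g.causal_idx, g.effect_sizes):
            eta += beta * G.dosages[:, idx[local_j]]
    return eta


def _liability_threshold(eta: np.ndarray, sd: float, prevalence: float) -> float:
    """t such that the average case probability P(eta_i + e > t) = prevalence."""

    def excess(t):
        return np.mean(stats.norm.sf((t - eta) / sd)) - prevalence

    lo = eta.min() - 10 * sd
    hi = eta.max() + 10 * sd
    return float(optimize.brentq(excess, lo, hi))


def simulate_phenotypes(G: GenotypeMatrix, config: SimulationConfig) -> ReplicateSet:
    """Re-simulate the trait ``n_replicates`` times over the fixed genotypes.

    Quantitative model per replicate:
    y = b0 + sum_causal beta_j x_j + g_age age + g_sex sex + e,
    e ~ N(0, noise_sd^2).  Covariates are drawn once and fixed with the
    genotypes.  The liability model thresholds the same quantitative
    liability at the configured prevalence.
    """
    _, _, rng = _streams(config.seed)
    cov = _draw_covariates(config)
    g_age, g_sex = config.covariate_effects
    eta = (
        config.beta0
        + _genetic_predictor(G, config)
        + g_age * cov[:, 0]
        + g_sex * cov[:, 1]
    )
    eps = rng.normal(0.0, config.noise_sd, size=(config.n_replicates, config.n_samples))
    liab = eta[None, :] + eps
    if config.trait_model == "gaussian":
        Y, family = liab, "gaussian"
    else:
        thr = _liability_threshold(eta, config.noise_sd, config.prevalence)
        Y, family = (liab > thr).astype(float), "binomial"
    return ReplicateSet(
        genotype=G,
        covariates=cov,
        covariate_names=["age", "sex"],
        phenotypes=Y,
        family=family,
        truth=config.truth,
        gene_map=gene_map_from_config(config),
        config=config,
    )


def simulate_bp_replicates(G: GenotypeMatrix, config: SimulationConfig):
    """Correlated SBP/DBP replicates on the mm Hg scale, plus HTN status.

    Both pressures share the scenario's genetic predictor and a common
    noise component (correlation ~0.6), on top of typical adult means
    (120/80 mm Hg, sd 15/10); 10% of samples carry a medication flag.
    Returns dict with 'SBP', 'DBP' (n_replicates x n), 'HTN', and 'med'.
    """
    _, _, rng = _streams(config.seed)
    cov = _draw_covariates(config)
    g_age, g_sex = config.covariate_effects
    eta = _genetic_predictor(G, config) + g_age * cov[:, 0] + g_sex * cov[:, 1]
    shape = (config.n_replicates, config.n_samples)
    shared = rng.standard_normal(shape)
    e_s = np.sqrt(0.6) * shared + np.sqrt(0.4) * rng.standard_normal(shape)
    e_d = np.sqrt(0.6) * shared + np.sqrt(0.4) * rng.standard_normal(shape)
    sbp = 120.0 + 15.0 * (eta[None, :] + e_s)
    dbp = 80.0 + 10.0 * (eta[None, :] + e_d)
    med = rng.binomial(1, 0.1, size=config.n_samples).astype(float)
    htn = derive_htn(sbp, dbp, np.broadcast_to(med, shape))
    return {"SBP": sbp, "DBP": dbp, "HTN": htn, "med": med, "covariates": cov}


def default_scenario(seed: int = 0) -> SimulationConfig:
    """Miniature version of the full-scale benchmark scenario.

    30 causal and 100 noncausal genes of 50-500 SNVs; causal genes carry
    2-8 causal SNVs with |beta| = 0.5, mixed directions in half of them;
    one driver gene holds a single dominant-effect SNV (beta = 1.0)
    among noise SNVs, exercising the loading-ranking feature.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    genes: list[GeneSpec] = []
    # the driver gene: one strong moderate-frequency causal SNV among
    # 49 noise SNVs
    genes.append(
        GeneSpec("driver0", 50, causal_idx=(7,), effect_sizes=(1.0,), causal_maf=(0.1,))
    )
    for i in range(29):
        p = int(rng.integers(50, 501))
        k = int(rng.integers(2, 9))
        idx = tuple(int(j) for j in np.sort(rng.choice(p, size=k, replace=False)))
        if i % 2 == 0:  # mixed-direction genes
            signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        else:
            signs = np.ones(k)
        genes.append(GeneSpec(f"causal{i:02d}", p, idx, tuple(0.5 * signs)))
    for i in range(100):
        genes.append(GeneSpec(f"null{i:03d}", int(rng.integers(50, 501))))
    return SimulationConfig(genes=genes, seed=seed)


def small_scenario(seed: int = 0, n_replicates: int = 10) -> SimulationConfig:
    """Tiny smoke-test scenario: 2 causal + 3 null genes, 10 SNVs each."""
    genes = [
        GeneSpec("causalA", 10, (0, 3), (0.8, -0.8)),
        GeneSpec("causalB", 10, (5,), (1.0,)),
        GeneSpec("null0", 10),
        GeneSpec("null1", 10),
        GeneSpec("null2", 10),
    ]
    return SimulationConfig(genes=genes, n_replicates=n_replicates, seed=seed)


def _plainify(obj):
    if isinstance(obj, (tuple, list)):
        return [_plainify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_scenario(config: SimulationConfig, path) -> None:
    """Write a scenario to JSON or YAML (by extension)."""
    d = _plainify(asdict(config))
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
    else:
        import json

        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def load_scenario(path) -> SimulationConfig:
    """Read a scenario config from JSON, YAML or TOML."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
    elif path.endswith(".toml"):
        import tomllib

        with open(path, "rb") as fh:
            d = tomllib.load(fh)
    else:
        import json

        with open(path) as fh:
            d = json.load(fh)
    d["genes"] = [GeneSpec(**{**g, "causal_idx": tuple(g.get("causal_idx", ())),
                              "effect_sizes": tuple(g.get("effect_sizes", ())),
                              "causal_maf": tuple(g.get("causal_maf", ()))})
                  for g in d.get("genes", [])]
    for key in ("maf_beta", "covariate_effects"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
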