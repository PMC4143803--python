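"""Replicate-design synthetic data generator."""

import numpy as np
import pytest
from scipy import stats

from rplskit.simulate import (
    GeneSpec,
    SimulationConfig,
    default_scenario,
    gene_intervals,
    gene_map_from_config,
    load_scenario,
    save_scenario,
    simulate_bp_replicates,
    simulate_genotypes,
    simulate_phenotypes,
    small_scenario,
)


def _cfg(**kw):
    base = dict(
        genes=[GeneSpec("gA", 8, (0,), (0.5,)), GeneSpec("gB", 8)],
        n_samples=200,
        n_replicates=20,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_reproducible_and_seed_sensitive(self):
        a = simulate_genotypes(_cfg())
        b = simulate_genotypes(_cfg())
        c = simulate_genotypes(_cfg(seed=12))
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_high_maf_binomial_moments(self):
        cfg = _cfg(maf_beta=(1e5, 1e5), n_samples=4000,
                   genes=[GeneSpec("g", 40)])  # maf pinned at ~0.5
        G = simulate_genotypes(cfg)
        assert G.dosages.mean() == pytest.approx(1.0, abs=0.03)
        assert G.dosages.var() == pytest.approx(0.5, abs=0.03)

    def test_rare_skewed_spectrum(self):
        cfg = SimulationConfig(
            genes=[GeneSpec("g", 10_000)], n_samples=2, seed=3,
            ensure_polymorphic=False,
        )
        G = simulate_genotypes(cfg)
        assert np.mean(G.maf < 0.05) > 0.5
        # drawn MAFs follow the configured min(Beta(0.2, 5), 0.5) spectrum
        ks = stats.kstest(G.maf, lambda x: stats.beta.cdf(x, 0.2, 5.0))
        assert ks.pvalue > 0.01

    def test_ld_copula_induces_neighbor_correlation(self):
        flat = _cfg(ld_rho=0.0, n_samples=1500, maf_beta=(5.0, 5.0),
                    genes=[GeneSpec("g", 12)])
        G0 = simulate_genotypes(flat)
        corr0 = np.corrcoef(G0.dosages, rowvar=False)
        off0 = corr0[np.triu_indices(12, 1)]
        assert abs(off0.mean()) < 0.02

        ld = _cfg(ld_rho=0.8, n_samples=1500, maf_beta=(5.0, 5.0),
                  genes=[GeneSpec("g", 12)])
        G1 = simulate_genotypes(ld)
        corr1 = np.corrcoef(G1.dosages, rowvar=False)
        adjacent = np.diag(corr1, k=1)
        assert adjacent.mean() > 0.4

    def test_causal_maf_override(self):
        cfg = _cfg(genes=[GeneSpec("g", 6, (2,), (1.0,), causal_maf=(0.25,))],
                   n_samples=5000)
        G = simulate_genotypes(cfg)
        assert G.maf[2] == 0.25
        assert G.dosages[:, 2].mean() / 2 == pytest.approx(0.25, abs=0.02)

    def test_positions_separate_genes(self):
        G = simulate_genotypes(_cfg())
        gmap_direct = gene_map_from_config(_cfg())
        from rplskit.io import build_gene_map

        gmap_by_pos = build_gene_map(gene_intervals(_cfg(), "bed"), G, "bed")
        for gene in ("gA", "gB"):
            np.testing.assert_array_equal(gmap_direct[gene], gmap_by_pos[gene])


class TestPhenotypes:
    def test_null_model_mean(self):
        cfg = _cfg(genes=[GeneSpec("g", 5)], beta0=2.0,
                   covariate_effects=(0.0, 0.0), n_replicates=50)
        reps = simulate_phenotypes(simulate_genotypes(cfg), cfg)
        se = cfg.noise_sd / np.sqrt(reps.phenotypes.size)
        assert reps.phenotypes.mean() == pytest.approx(2.0, abs=4 * se)

    def test_effect_recovery_by_ols(self):
        cfg = SimulationConfig(
            genes=[GeneSpec("g", 6, (1, 4), (0.7, -0.5), causal_maf=(0.2, 0.3))],
            n_samples=1000, n_replicates=1, seed=5,
        )
        G = simulate_genotypes(cfg)
        reps = simulate_phenotypes(G, cfg)
        y = reps.phenotypes[0]
        import statsmodels.api as sm

        design = sm.add_constant(
            np.column_stack([G.dosages[:, [1, 4]], reps.covariates])
        )
        fit = sm.OLS(y, design).fit()
        for est, se, truth in zip(fit.params[1:3], fit.bse[1:3], (0.7, -0.5)):
            assert abs(est - truth) < 2 * se + 1e-9

    def test_liability_threshold_prevalence(self):
        cfg = _cfg(trait_model="liability", prevalence=0.3, n_replicates=40)
        reps = simulate_phenotypes(simulate_genotypes(cfg), cfg)
        assert reps.family == "binomial"
        assert set(np.unique(reps.phenotypes)) <= {0.0, 1.0}
        frac = reps.phenotypes.mean()
        se = np.sqrt(0.3 * 0.7 / reps.phenotypes.size)
        assert frac == pytest.approx(0.3, abs=6 * se)

    def test_replicates_share_genotypes_and_covariates(self):
        cfg = _cfg()
        G = simulate_genotypes(cfg)
        reps = simulate_phenotypes(G, cfg)
        assert reps.phenotypes.shape == (20, 200)
        assert reps.genotype is G
        # replicates differ only in the noise draw
        assert not np.allclose(reps.phenotypes[0], reps.phenotypes[1])

    def test_truth_labels(self):
        reps = simulate_phenotypes(simulate_genotypes(_cfg()), _cfg())
        assert reps.truth == {"gA": True, "gB": False}

    def test_bp_traits(self):
        cfg = _cfg(n_replicates=5)
        out = simulate_bp_replicates(simulate_genotypes(cfg), cfg)
        assert out["SBP"].shape == (5, 200)
        assert np.all((out["HTN"] == 0) | (out["HTN"] == 1))
        assert 100 < out["SBP"].mean() < 140
        assert np.corrcoef(out["SBP"][0], out["DBP"][0])[0, 1] > 0.3


class TestScenarios:
    def test_default_scenario_shape(self):
        cfg = default_scenario()
        causal = [g for g in cfg.genes if g.is_causal]
        assert len(causal) == 30 and len(cfg.genes) == 130
        assert any(len(set(np.sign(g.effect_sizes))) == 2 for g in causal)
        assert all(50 <= g.n_snvs <= 500 for g in cfg.genes)

    def test_roundtrip_json_and_yaml(self, tmp_path):
        cfg = small_scenario(seed=9)
        for name in ("s.json", "s.yaml"):
            path = tmp_path / name
            save_scenario(cfg, path)
            back = load_scenario(path)
            assert back.seed == 9
            assert [g.name for g in back.genes] == [g.name for g in cfg.genes]
            a = simulate_genotypes(cfg)
            b = simulate_genotypes(back)
            np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_invalid_gene_spec(self):
        with pytest.raises(ValueError):
            GeneSpec("bad", 5, (7,), (1.0,))
        with pytest.raises(ValueError):
            GeneSpec("bad", 5, (1,), (1.0, 2.0))
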