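"""The two-step rPLS test: screening, supervariant, GLM inference."""

import numpy as np
import pytest
from scipy import stats

from rplskit._enet import enet_path_gram
from rplskit.estimators import RPLSTest
from rplskit.rpls import (
    DegeneratePLSError,
    RplsConfig,
    elastic_net_screen,
    glm_test_supervariant,
    pls_supervariant,
    rank_snvs,
    rpls_test,
)
from tests.conftest import draw_polymorphic_gene


class TestElasticNetScreen:
    def test_full_shrinkage_gives_empty_set(self, rng):
        X, _ = draw_polymorphic_gene(rng, 60, 5)
        Xs = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=60)
        lam_max = np.abs(Xs.T @ y).max() / (60 * 0.5)
        coefs = enet_path_gram(Xs, y - y.mean(), [lam_max * 1.01], l1_ratio=0.5)
        assert np.all(coefs == 0.0)

    def test_no_penalty_selects_associated_variant(self, rng):
        x = rng.binomial(2, 0.3, size=80).astype(float)
        y = 0.9 * x + rng.normal(size=80)
        Xs = ((x - x.mean()) / x.std())[:, None]
        coefs = enet_path_gram(Xs, y - y.mean(), [1e-8], l1_ratio=0.5)
        assert abs(coefs[0, 0]) > 0.1

    def test_matches_sklearn_path(self, rng):
        """Dual-route check of the coordinate descent against sklearn."""
        from sklearn.linear_model import enet_path

        X, _ = draw_polymorphic_gene(rng, 100, 8, maf_beta=(2.0, 5.0))
        Xs = (X - X.mean(0)) / X.std(0)
        y = 0.5 * Xs[:, 2] + rng.normal(size=100)
        y = y - y.mean()
        lam_max = np.abs(Xs.T @ y).max() / (100 * 0.5)
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, 30)
        mine = enet_path_gram(Xs, y, lambdas, l1_ratio=0.5)
        _, ref, _ = enet_path(Xs, y, l1_ratio=0.5, alphas=lambdas)
        np.testing.assert_allclose(mine, ref, atol=2e-4)

    def test_monte_carlo_selects_causal(self, rng):
        """One causal SNV (effect 1.0, maf 0.3) among 20 null SNVs, n=500."""
        hits = 0
        for rep in range(100):
            X = rng.binomial(2, np.r_[0.3, np.full(20, 0.2)], size=(500, 21)).astype(float)
            y = 1.0 * X[:, 0] + rng.normal(size=500)
            sel = elastic_net_screen(X, y, seed=rep)
            hits += 0 in sel
        assert hits >= 95

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 10"):
            elastic_net_screen(np.zeros((5, 3)), np.zeros(5))


class TestPlsSupervariant:
    def test_single_column_reduction(self, rng):
        x = rng.binomial(2, 0.4, size=40).astype(float)
        y = x + rng.normal(size=40)
        w, t = pls_supervariant(x[:, None], y - y.mean())
        assert abs(abs(w[0]) - 1.0) < 1e-12
        np.testing.assert_allclose(t, (x - x.mean()) * w[0], atol=1e-12)

    def test_loading_from_covariances(self):
        """Orthogonal columns with cov 0.4 / 0.3 give loading (0.8, 0.6)."""
        n = 8
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        assert abs(x1 @ x2) < 1e-12
        y = 0.4 * x1 + 0.3 * x2  # X'y = (0.4n, 0.3n)
        w, t = pls_supervariant(np.column_stack([x1, x2]), y)
        np.testing.assert_allclose(w, [0.8, 0.6], atol=1e-12)
        np.testing.assert_allclose(t, np.column_stack([x1, x2]) @ w, atol=1e-12)
        assert abs(np.linalg.norm(w) - 1) < 1e-12

    def test_orthogonal_response_raises(self):
        x1 = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(DegeneratePLSError):
            pls_supervariant(x1[:, None], y)


class TestGlmTestSupervariant:
    def test_gaussian_equals_classical_t_test(self, rng):
        t_var = rng.normal(size=60)
        y = 0.3 * t_var + rng.normal(size=60)
        beta, p, details = glm_test_supervariant(t_var, None, y, "gaussian")
        lin = stats.linregress(t_var, y)
        assert p == pytest.approx(lin.pvalue, abs=1e-12)
        assert beta == pytest.approx(lin.slope, abs=1e-12)

    def test_binomial_separation_flagged(self):
        t_var = np.r_[np.zeros(20), np.ones(20)] + 0.0
        y = (t_var > 0.5).astype(float)
        beta, p, details = glm_test_supervariant(
            t_var + np.linspace(0, 0.01, 40), None, y, "binomial"
        )
        assert p == 1.0 and "perfect_separation" in details["flags"]


class TestRplsTest:
    def test_constant_trait_gives_empty_selection(self, rng):
        X, _ = draw_polymorphic_gene(rng, 50, 6)
        fit = rpls_test(X, np.zeros(50))
        assert fit.k == 0 and fit.p_value == 1.0 and fit.snv_ranking == []

    def test_single_column_gene_reduces_to_glm_wald(self, rng):
        x = rng.binomial(2, 0.3, size=100).astype(float)
        Z = rng.normal(size=(100, 2))
        y = 0.8 * x + Z @ [0.2, -0.1] + rng.normal(size=100)
        fit = rpls_test(x[:, None], y, Z)
        assert fit.k == 1
        from rplskit._glm import wald_1df

        _, _, p_ref, _, _ = wald_1df(x, Z, y, "gaussian")
        assert fit.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        X, _ = draw_polymorphic_gene(rng, 80, 10)
        y = 0.5 * X[:, 4] + rng.normal(size=80)
        cfg = RplsConfig(seed=7)
        a = rpls_test(X, y, config=cfg)
        b = rpls_test(X, y, config=cfg)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.selected_idx, b.selected_idx)
        np.testing.assert_array_equal(a.loading_w, b.loading_w)

    def test_scale_equivariance_gaussian(self, rng):
        X, _ = draw_polymorphic_gene(rng, 90, 8)
        y = 0.6 * X[:, 1] + rng.normal(size=90)
        a = rpls_test(X, y)
        b = rpls_test(X, 3.5 * y)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)
        np.testing.assert_array_equal(a.selected_idx, b.selected_idx)

    def test_binomial_family_runs(self, rng):
        X, _ = draw_polymorphic_gene(rng, 120, 4, maf_beta=(2.0, 5.0))
        eta = -0.3 + 1.2 * X[:, 0]
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = rpls_test(X, y, family="binomial", config=RplsConfig(family="binomial", n_lambdas=10, cv_folds=5))
        assert 0.0 <= fit.p_value <= 1.0

    def test_estimator_interface(self, rng):
        """get_params/set_params/clone work as for any sklearn estimator."""
        from sklearn.base import clone

        est = RPLSTest(en_alpha=0.7, seed=3)
        est2 = clone(est)
        assert est2.get_params()["en_alpha"] == 0.7
        X, _ = draw_polymorphic_gene(rng, 60, 5)
        y = rng.normal(size=60)
        est2.set_params(seed=5).fit(X, y)
        assert hasattr(est2, "p_value_")


class TestRankSnvs:
    def _fit(self, w, ids, pos):
        from rplskit.rpls import RplsFit

        return RplsFit(
            selected_idx=np.arange(len(w)),
            loading_w=np.asarray(w, dtype=float),
            supervariant_t=None,
            beta_star=0.0,
            beta0=0.0,
            gamma=np.empty(0),
            p_value=0.5,
            snv_ranking=[],
            variant_ids=ids,
            positions=np.asarray(pos, dtype=float),
        )

    def test_absolute_value_order(self):
        fit = self._fit([0.8, -0.6], ["v1", "v2"], [10, 20])
        assert rank_snvs(fit) == ["v1", "v2"]
        fit = self._fit([-0.6, 0.8], ["v1", "v2"], [10, 20])
        assert rank_snvs(fit) == ["v2", "v1"]

    def test_tie_broken_by_position(self):
        fit = self._fit([0.6, -0.6], ["far", "near"], [500, 100])
        assert rank_snvs(fit) == ["near", "far"]

    def test_singleton(self):
        fit = self._fit([1.0], ["only"], [42])
        assert rank_snvs(fit) == ["only"]
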