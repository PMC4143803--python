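"""SUM, SKAT and SKAT-O comparison tests."""

import numpy as np
import pytest
from scipy import stats

from rplskit._glm import fit_null, wald_1df
from rplskit.competing import skat_o_test, skat_test, sum_test
from rplskit.estimators import SKATOTest, SKATTest, SumTest
from tests.conftest import draw_polymorphic_gene


def _score_test_oracle(s, Z, y):
    """1-df gaussian score test of supervariant s, plug-in sigma_hat^2."""
    null = fit_null(y, Z, "gaussian")
    coef, *_ = np.linalg.lstsq(null.X0, s, rcond=None)
    sr = s - null.X0 @ coef
    stat = (s @ null.resid) ** 2 / (null.sigma2 * (sr @ sr))
    return stats.chi2.sf(stat, df=1)


class TestSum:
    def test_row_sums(self):
        est = SumTest().fit(
            np.array([[0.0, 1.0], [2.0, 0.0], [1.0, 1.0]]),
            np.array([0.1, 0.2, 0.3]),
        )
        np.testing.assert_array_equal(est.supervariant_, [1, 2, 2])

    def test_all_zero_gene(self, rng):
        est = SumTest().fit(np.zeros((20, 3)), rng.normal(size=20))
        assert est.p_value_ == 1.0 and "constant_supervariant" in est.flags_

    def test_one_snv_reduces_to_glm(self, rng):
        x = rng.binomial(2, 0.3, size=60).astype(float)
        Z = rng.normal(size=(60, 1))
        y = 0.5 * x + rng.normal(size=60)
        est = SumTest().fit(x[:, None], y, Z=Z)
        _, _, p_ref, _, _ = wald_1df(x, Z, y, "gaussian")
        assert est.p_value_ == pytest.approx(p_ref, abs=1e-12)

    def test_mixed_directions_weaken_sum(self, rng):
        """Equal-magnitude opposite effects cancel in the burden score."""
        X, _ = draw_polymorphic_gene(rng, 300, 6, maf_beta=(2.0, 5.0))
        noise = rng.normal(size=300)
        y_aligned = X @ np.full(6, 0.4) + noise
        y_mixed = X @ (0.4 * np.array([1, -1, 1, -1, 1, -1.0])) + noise
        p_aligned = SumTest().fit(X, y_aligned).p_value_
        p_mixed = SumTest().fit(X, y_mixed).p_value_
        assert p_aligned < p_mixed

    def test_wrapper_row(self, rng):
        X, _ = draw_polymorphic_gene(rng, 40, 3)
        res = sum_test(X, rng.normal(size=40), gene="g1")
        assert res.method == "SUM" and res.gene == "g1"
        assert 0 <= res.p_value <= 1


class TestSkat:
    def test_single_variant_exact_equals_t_test(self, rng):
        x = rng.binomial(2, 0.25, size=120).astype(float)
        Z = rng.normal(size=(120, 2))
        y = rng.normal(size=120)
        est = SKATTest(flat_weights=True).fit(x[:, None], y, Z=Z)
        _, _, p_t, _, _ = wald_1df(x, Z, y, "gaussian")
        assert est.p_value_ == pytest.approx(p_t, abs=1e-9)

    def test_single_variant_asymptotic_equals_score_test(self, rng):
        x = rng.binomial(2, 0.25, size=120).astype(float)
        Z = rng.normal(size=(120, 2))
        y = rng.normal(size=120)
        est = SKATTest(flat_weights=True, exact_gaussian=False).fit(x[:, None], y, Z=Z)
        assert est.p_value_ == pytest.approx(_score_test_oracle(x, Z, y), abs=1e-12)

    def test_zero_statistic_gives_p_one(self, rng):
        x = rng.binomial(2, 0.4, size=12).astype(float)
        xc = x - x.mean()
        y = rng.normal(size=12)
        # make the null residuals exactly orthogonal to the variant
        y = y - (xc @ (y - y.mean())) / (xc @ xc) * xc
        est = SKATTest(flat_weights=True).fit(x[:, None], y)
        assert est.statistic_ == pytest.approx(0.0, abs=1e-18)
        assert est.p_value_ == 1.0

    def test_binomial_single_variant_equals_score_test(self, rng):
        x = rng.binomial(2, 0.3, size=200).astype(float)
        Z = rng.normal(size=(200, 1))
        eta = -0.4 + 0.3 * Z[:, 0]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        est = SKATTest(family="binomial", flat_weights=True).fit(x[:, None], y, Z=Z)
        null = fit_null(y, Z, "binomial")
        v = null.irls_w
        X0 = null.X0
        proj = X0 @ np.linalg.solve(X0.T @ (v[:, None] * X0), X0.T @ (v * x))
        var = (x - proj) @ (v * (x - proj))
        stat = (x @ null.resid) ** 2 / var
        assert est.p_value_ == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-9)

    def test_permutation_agreement_small(self, rng):
        """Analytic SKAT p matches the genotype-permutation null (n=50)."""
        n, n_perm = 50, 20000
        X, maf = draw_polymorphic_gene(rng, n, 8)
        y = 0.4 * X[:, 2] + rng.normal(size=n)
        est = SKATTest().fit(X, y, maf=maf)
        w = est.weights_
        yc = y - y.mean()
        u_obs = (X * w).T @ yc
        obs = float(u_obs @ u_obs)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        Yp = yc[perm_idx]  # (n_perm, n)
        U = Yp @ (X * w)  # (n_perm, 8)
        q_perm = np.sum(U * U, axis=1)
        p_perm = (1 + np.sum(q_perm >= obs - 1e-12)) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert est.p_value_ == pytest.approx(p_perm, abs=3 * se)

    def test_weight_spectrum_upweights_rare(self):
        from rplskit.estimators import beta_maf_weights

        w_rare, w_common = beta_maf_weights([0.005, 0.4])
        assert w_rare > w_common
        with pytest.raises(ValueError):
            beta_maf_weights([0.7])


class TestSkatO:
    def test_rho_zero_grid_equals_skat(self, rng):
        X, maf = draw_polymorphic_gene(rng, 80, 6)
        y = 0.3 * X[:, 0] + rng.normal(size=80)
        p_skato = SKATOTest(rho_grid=(0.0,)).fit(X, y, maf=maf).p_value_
        p_skat = SKATTest(exact_gaussian=False).fit(X, y, maf=maf).p_value_
        assert p_skato == pytest.approx(p_skat, abs=1e-12)

    def test_rho_one_flat_weights_equals_burden_score(self, rng):
        X, _ = draw_polymorphic_gene(rng, 80, 5)
        Z = rng.normal(size=(80, 1))
        y = 0.3 * X.sum(axis=1) + rng.normal(size=80)
        p_skato = SKATOTest(rho_grid=(1.0,), flat_weights=True).fit(X, y, Z=Z).p_value_
        assert p_skato == pytest.approx(_score_test_oracle(X.sum(axis=1), Z, y), abs=1e-9)

    def test_min_p_bracket(self, rng):
        """Grid-corrected p lies between min-p and the Bonferroni bound."""
        for trial in range(5):
            X, maf = draw_polymorphic_gene(rng, 100, 7)
            y = 0.35 * X[:, 1] - 0.3 * X[:, 4] + rng.normal(size=100)
            est = SKATOTest().fit(X, y, maf=maf)
            min_p = float(np.min(est.p_values_rho_))
            assert min_p - 1e-12 <= est.p_value_ <= min(1.0, 8 * min_p) + 1e-12

    def test_reports_optimal_rho(self, rng):
        X, maf = draw_polymorphic_gene(rng, 70, 5)
        y = 0.5 * X.sum(axis=1) + rng.normal(size=70)
        res = skat_o_test(X, y, maf=maf, gene="g")
        assert res.method == "SKAT-O"
        assert 0.0 <= res.df_or_params["rho_opt"] <= 1.0

    def test_bad_grid_rejected(self, rng):
        X, _ = draw_polymorphic_gene(rng, 40, 3)
        with pytest.raises(ValueError):
            SKATOTest(rho_grid=(0.0, 1.5)).fit(X, rng.normal(size=40))


def test_result_rows_have_valid_pvalues(rng):
    X, maf = draw_polymorphic_gene(rng, 60, 4)
    y = rng.normal(size=60)
    for res in (
        sum_test(X, y),
        skat_test(X, y, maf=maf),
        skat_o_test(X, y, maf=maf),
    ):
        assert 0.0 <= res.p_value <= 1.0
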