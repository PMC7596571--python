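import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pelletscape.model import (
    concentrated_loglik,
    fit_spatial_fe,
    fit_spatial_re,
    hausman_test,
    re_loglik,
    coef_table,
)
from conftest import random_weights


def dense_loglik_oracle(beta, rho, s2mu, s2nu, Y, Z, W):
    """Naive NT×NT multivariate-normal evaluation of the model density."""
    T, N = Y.shape
    B = np.eye(N) - rho * W
    Binv = np.linalg.inv(B)
    A = Binv @ Binv.T
    Sigma = np.kron(s2mu * np.ones((T, T)) + s2nu * np.eye(T), A)
    mean = (beta[0] + np.einsum("tnk,k->tn", Z, beta[1:])).reshape(-1)
    return multivariate_normal.logpdf(Y.reshape(-1), mean, Sigma)


def simulate(rng, wm, T=5, K=3, beta=None, rho=0.4, s2mu=1.0, s2nu=1.0):
    N = wm.n
    if beta is None:
        beta = np.concatenate([[2.0], rng.normal(0, 1, K)])
    Z = rng.normal(size=(T, N, K))
    B = np.eye(N) - rho * wm.W
    mu = rng.normal(0, math.sqrt(s2mu), N) if s2mu > 0 else np.zeros(N)
    nu = rng.normal(0, math.sqrt(s2nu), (T, N))
    u = np.linalg.solve(B, (mu[None, :] + nu).T).T
    Y = beta[0] + np.einsum("tnk,k->tn", Z, beta[1:]) + u
    return Y, Z, beta


class TestLoglik:
    def test_matches_dense_oracle(self, rng):
        wm = random_weights(rng, 10)
        Y, Z, beta = simulate(rng, wm, T=3)
        for _ in range(10):
            rho = rng.uniform(-0.9, 0.9)
            s2mu = rng.uniform(0.0, 3.0)
            s2nu = rng.uniform(0.2, 3.0)
            b = beta + rng.normal(0, 0.3, beta.shape)
            ll = re_loglik(b, rho, s2mu, s2nu, Y, Z, wm.W)
            oracle = dense_loglik_oracle(b, rho, s2mu, s2nu, Y, Z, wm.W)
            assert ll == pytest.approx(oracle, rel=1e-10, abs=1e-8)

    def test_iid_limit_is_gaussian_regression(self, rng):
        wm = random_weights(rng, 8)
        Y, Z, beta = simulate(rng, wm, T=3, rho=0.0, s2mu=0.0)
        s2 = 1.7
        ll = re_loglik(beta, 0.0, 0.0, s2, Y, Z, wm.W)
        resid = Y - beta[0] - np.einsum("tnk,k->tn", Z, beta[1:])
        nt = Y.size
        expected = -0.5 * nt * math.log(2 * math.pi * s2) - 0.5 * (resid**2).sum() / s2
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_scaling_change_of_variables(self, rng):
        wm = random_weights(rng, 8)
        Y, Z, beta = simulate(rng, wm, T=3)
        c = 3.5
        args = (0.3, 0.8, 1.2)
        ll = re_loglik(beta, *args, Y, Z, wm.W)
        ll_scaled = re_loglik(
            beta * c, args[0], args[1] * c**2, args[2] * c**2, Y * c, Z, wm.W
        )
        assert ll_scaled == pytest.approx(ll - Y.size * math.log(c), rel=1e-10)

    def test_invalid_parameters_rejected(self, rng):
        wm = random_weights(rng, 6)
        Y, Z, beta = simulate(rng, wm, T=3)
        with pytest.raises(ValueError):
            re_loglik(beta, 1.2, 1.0, 1.0, Y, Z, wm.W)
        with pytest.raises(ValueError):
            re_loglik(beta, 0.1, -0.5, 1.0, Y, Z, wm.W)
        with pytest.raises(ValueError):
            re_loglik(beta, 0.1, 1.0, 0.0, Y, Z, wm.W)


class TestFitRE:
    def test_concentrated_consistent_with_full(self, rng):
        wm = random_weights(rng, 12)
        Y, Z, _ = simulate(rng, wm)
        fit = fit_spatial_re(Y, Z, wm.W)
        full = re_loglik(fit.params, fit.rho, fit.sigma2_mu_ml, fit.sigma2_nu_ml, Y, Z, wm.W)
        assert fit.loglik == pytest.approx(full, rel=1e-10)
        prof = concentrated_loglik(fit.rho, fit.theta, Y, Z, wm.W)
        assert fit.loglik == pytest.approx(prof, rel=1e-10)

    def test_optimum_beats_neighbourhood(self, rng):
        wm = random_weights(rng, 15)
        Y, Z, _ = simulate(rng, wm)
        fit = fit_spatial_re(Y, Z, wm.W)
        for drho in (-0.05, 0.05):
            for dth in (-0.05, 0.05):
                th = max(0.0, fit.theta + dth)
                assert concentrated_loglik(fit.rho + drho, th, Y, Z, wm.W) <= fit.loglik + 1e-9

    def test_recovers_truth_on_average(self, rng):
        wm = random_weights(rng, 60)
        beta = np.array([2.0, 1.0, -1.5, 0.5])
        fits = []
        for _ in range(15):
            Y, Z, _ = simulate(rng, wm, T=5, beta=beta, rho=0.5, s2mu=1.0, s2nu=1.0)
            fits.append(fit_spatial_re(Y, Z, wm.W))
        assert all(f.converged for f in fits)
        assert np.mean([f.rho for f in fits]) == pytest.approx(0.5, abs=0.15)
        np.testing.assert_allclose(
            np.mean([f.params for f in fits], axis=0), beta, atol=0.3
        )
        fit = fits[0]
        assert fit.p.shape == fit.params.shape
        assert np.all((fit.p >= 0) & (fit.p <= 1))
        # vcov symmetric positive semidefinite
        np.testing.assert_allclose(fit.vcov, fit.vcov.T, rtol=1e-10)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-12)

    def test_too_many_coefficients_rejected(self, rng):
        wm = random_weights(rng, 4)
        Y, Z, _ = simulate(rng, wm, T=3, K=15)
        with pytest.raises(ValueError):
            fit_spatial_re(Y, Z, wm.W)


class TestFitFE:
    def test_unit_shift_invariance(self, rng):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm)
        fe1 = fit_spatial_fe(Y, Z, wm.W)
        shift = rng.normal(0, 10, wm.n)
        fe2 = fit_spatial_fe(Y + shift[None, :], Z, wm.W)
        np.testing.assert_allclose(fe1.params, fe2.params, rtol=1e-8, atol=1e-10)
        assert fe1.rho == pytest.approx(fe2.rho, abs=1e-6)

    def test_demeaned_columns_sum_to_zero(self, rng):
        wm = random_weights(rng, 10)
        Y, Z, _ = simulate(rng, wm)
        Zd = Z - Z.mean(axis=0)
        np.testing.assert_allclose(Zd.sum(axis=0), 0.0, atol=1e-12)

    def test_time_invariant_column_rejected(self, rng):
        wm = random_weights(rng, 10)
        Y, Z, _ = simulate(rng, wm, K=2)
        Zbad = np.concatenate([Z, np.ones((5, 10, 1))], axis=2)
        with pytest.raises(ValueError):
            fit_spatial_fe(Y, Zbad, wm.W)

    def test_agrees_with_re_when_no_unit_effects(self, rng):
        wm = random_weights(rng, 80)
        beta = np.array([1.0, 2.0, -1.0])
        Y, Z, _ = simulate(rng, wm, T=5, K=2, beta=beta, rho=0.3, s2mu=0.0, s2nu=1.0)
        re = fit_spatial_re(Y, Z, wm.W)
        fe = fit_spatial_fe(Y, Z, wm.W)
        np.testing.assert_allclose(fe.params, re.params[1:], atol=0.15)


class TestHausman:
    def test_identical_estimates_give_zero(self, rng):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm)
        re = fit_spatial_re(Y, Z, wm.W, names=["a", "b", "c"])
        fe = fit_spatial_fe(Y, Z, wm.W, names=["a", "b", "c"])
        fe.params = re.params[1:].copy()
        fe.vcov = re.vcov[1:, 1:] * 2.0
        h = hausman_test(fe, re)
        assert h.statistic == pytest.approx(0.0, abs=1e-12)
        assert h.p == pytest.approx(1.0)
        assert h.decision == "random"

    def test_hand_arithmetic_toy(self, rng):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm, K=2)
        re = fit_spatial_re(Y, Z, wm.W, names=["a", "b"])
        fe = fit_spatial_fe(Y, Z, wm.W, names=["a", "b"])
        fe.params = re.params[1:] + np.array([1.0, 0.0])
        fe.vcov = re.vcov[1:, 1:] + np.eye(2)
        h = hausman_test(fe, re)
        assert h.statistic == pytest.approx(1.0, rel=1e-10)
        assert h.dof == 2

    def test_pseudo_inverse_flagged(self, rng):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm, K=2)
        re = fit_spatial_re(Y, Z, wm.W, names=["a", "b"])
        fe = fit_spatial_fe(Y, Z, wm.W, names=["a", "b"])
        fe.vcov = re.vcov[1:, 1:] - np.eye(2)  # negative-definite difference
        h = hausman_test(fe, re)
        assert h.used_pseudo_inverse
        assert h.statistic >= 0.0

    def test_no_shared_names_rejected(self, rng):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm)
        re = fit_spatial_re(Y, Z, wm.W, names=["a", "b", "c"])
        fe = fit_spatial_fe(Y, Z, wm.W, names=["x", "y", "z"])
        with pytest.raises(ValueError):
            hausman_test(fe, re)


class TestCoefTable:
    def test_layout_and_p_convention(self, rng):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm)
        fit = fit_spatial_re(Y, Z, wm.W, names=["a", "b", "c"])
        table = coef_table(fit)
        assert list(table.index) == ["intercept", "a", "b", "c"]
        assert set(table.columns) == {"coefficient", "std_error", "z", "p"}
        # two-sided normal convention: p agrees with 2*Phi(-|z|) rowwise
        from scipy.stats import norm

        np.testing.assert_allclose(table["p"], 2 * norm.sf(np.abs(table["z"])), rtol=1e-12)

    def test_roundtrip_csv_12_digits(self, rng, tmp_path):
        wm = random_weights(rng, 20)
        Y, Z, _ = simulate(rng, wm)
        fit = fit_spatial_re(Y, Z, wm.W, names=["a", "b", "c"])
        table = coef_table(fit)
        path = tmp_path / "coef.csv"
        table.to_csv(path, float_format="%.12g")
        import pandas as pd

        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(
            back["coefficient"], table["coefficient"], rtol=1e-11
        )
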