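import numpy as np
import pytest
from scipy import stats

from longqtl import build_covariance, get_covariance, mvn_logpdf, register_covariance, select_covariance
from longqtl.covariance import (
    _REGISTRY,
    NotPositiveDefiniteError,
    RegistryError,
    arma11_acf_coeffs,
    fit_covariance_ml,
    list_covariances,
    pacf_to_acf,
)
from tests.oracles import ar1_loglik_tridiagonal, naive_mvn_logpdf, sad1_covariance_by_simulation

STRUCTURES = ["VC", "CS", "AR1", "AR1_time", "ARMA11", "TOEP", "SAD1"]


def random_theta(model, m, rng):
    """In-bounds parameter draw; variances in a moderate range."""
    theta = []
    for lo, hi in model.param_bounds(m):
        if hi == np.inf:
            theta.append(float(rng.uniform(0.1, 5.0)))
        else:
            margin = 0.02 * (hi - lo)
            theta.append(float(rng.uniform(lo + margin, hi - margin)))
    return np.array(theta)


class TestBuild:
    def test_ar1_rho_zero_is_diagonal(self):
        np.testing.assert_allclose(build_covariance("AR1", [2.0, 0.0], 3), 2.0 * np.eye(3))

    def test_ar1_determinant_closed_form(self):
        m, s2, rho = 3, 1.0, 0.5
        sigma = build_covariance("AR1", [s2, rho], m)
        det = np.linalg.det(sigma)
        assert det == pytest.approx((1 - rho**2) ** (m - 1), abs=1e-12)
        assert det == pytest.approx(0.5625, abs=1e-12)

    def test_cs_boundary(self):
        m = 4
        lo = -1.0 / (m - 1)
        sigma = build_covariance("CS", [1.0, lo + 1e-6], m)
        np.linalg.cholesky(sigma)  # PD just inside the bound
        boundary = 1.0 * ((1.0 - lo) * np.eye(m) + lo * np.ones((m, m)))
        assert np.linalg.det(boundary) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_name(self):
        with pytest.raises(RegistryError):
            build_covariance("UNSTRUCTURED", [1.0], 3)

    def test_out_of_bounds_theta(self):
        with pytest.raises(ValueError):
            build_covariance("AR1", [1.0, 1.5], 3)

    def test_ar1_time_uses_calendar_distance(self):
        times = np.array([0.0, 1.0, 3.0])
        sigma = build_covariance("AR1_time", [1.0, 0.5], 3, times)
        assert sigma[0, 1] == pytest.approx(0.5)
        assert sigma[1, 2] == pytest.approx(0.25)
        assert sigma[0, 2] == pytest.approx(0.125)

    def test_arma11_reduces_to_ar1_when_psi_zero(self):
        m = 5
        for rho in (-0.4, 0.3, 0.8):
            np.testing.assert_allclose(
                build_covariance("ARMA11", [1.3, rho, 0.0], m),
                build_covariance("AR1", [1.3, rho], m),
                atol=1e-12,
            )

    def test_arma11_acf_coeffs(self):
        gamma, rho = arma11_acf_coeffs(0.5, 0.2)
        # textbook ARMA(1,1) lag-1 autocorrelation
        expected = (1 + 0.5 * 0.2) * (0.5 + 0.2) / (1 + 2 * 0.5 * 0.2 + 0.2**2)
        assert gamma == pytest.approx(expected)
        assert rho == 0.5

    def test_sad1_matches_simulation(self, rng):
        v = np.array([1.0, 0.8, 1.2, 0.9])
        phi = np.array([0.7, 0.5, 0.9])
        sigma = build_covariance("SAD1", np.concatenate([v, phi]), 4)
        emp = sad1_covariance_by_simulation(v, phi, 200_000, rng)
        np.testing.assert_allclose(sigma, emp, atol=0.05)

    def test_toeplitz_lag1(self):
        sigma = build_covariance("TOEP", [2.0, 0.5, 0.0], 3)
        assert sigma[0, 1] == pytest.approx(2.0 * 0.5)
        assert sigma[0, 0] == pytest.approx(2.0)

    def test_pacf_to_acf_lag1(self):
        np.testing.assert_allclose(pacf_to_acf(np.array([0.6])), [0.6])
        # AR(1)-like: constant pacf decay of an AR(1) is (rho, 0, 0, ...)
        np.testing.assert_allclose(pacf_to_acf(np.array([0.6, 0.0, 0.0])), [0.6, 0.36, 0.216], atol=1e-12)


class TestPDProperty:
    @pytest.mark.parametrize("name", STRUCTURES)
    def test_symmetric_and_cholesky_for_random_draws(self, name, rng):
        model = get_covariance(name)
        m = 6
        times = np.arange(1.0, 7.0)
        for _ in range(1000):
            theta = random_theta(model, m, rng)
            sigma = model.build(theta, m, times)
            np.testing.assert_array_equal(sigma, sigma.T)
            np.linalg.cholesky(sigma)  # raises if not PD


class TestMvnLogpdf:
    def test_standard_normal(self):
        assert mvn_logpdf(np.array([0.0]), np.array([0.0]), np.array([[1.0]])) == pytest.approx(
            -0.9189385332046727, abs=1e-12
        )

    def test_diagonal_factorizes(self, rng):
        y = rng.normal(size=4)
        mean = rng.normal(size=4)
        var = rng.uniform(0.5, 2.0, 4)
        got = mvn_logpdf(y, mean, np.diag(var))
        expected = sum(stats.norm.logpdf(y[i], mean[i], np.sqrt(var[i])) for i in range(4))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_random_5dim_vs_oracle(self, rng):
        for _ in range(20):
            A = rng.normal(size=(5, 5))
            sigma = A @ A.T + 5 * np.eye(5)
            y, mean = rng.normal(size=5), rng.normal(size=5)
            assert mvn_logpdf(y, mean, sigma) == pytest.approx(naive_mvn_logpdf(y, mean, sigma), abs=1e-10)

    def test_missing_marginalizes(self, rng):
        A = rng.normal(size=(4, 4))
        sigma = A @ A.T + 4 * np.eye(4)
        y = rng.normal(size=4)
        y_miss = y.copy()
        y_miss[2] = np.nan
        keep = [0, 1, 3]
        expected = naive_mvn_logpdf(y[keep], np.zeros(3), sigma[np.ix_(keep, keep)])
        assert mvn_logpdf(y_miss, np.zeros(4), sigma) == pytest.approx(expected, abs=1e-10)

    def test_non_pd_raises(self):
        sigma = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NotPositiveDefiniteError):
            mvn_logpdf(np.zeros(2), np.zeros(2), sigma)

    def test_ar1_closed_form(self, rng):
        """Cholesky log-density equals the tridiagonal-inverse AR(1) form."""
        for m in (2, 5, 11):
            y = rng.normal(size=m)
            s2, rho = 1.7, 0.62
            sigma = build_covariance("AR1", [s2, rho], m)
            assert mvn_logpdf(y, np.zeros(m), sigma) == pytest.approx(
                ar1_loglik_tridiagonal(y, np.zeros(m), s2, rho), abs=1e-9
            )


def simulate_residuals(name, theta, n, m, rng, times=None):
    sigma = build_covariance(name, theta, m, times)
    L = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, m)) @ L.T


class TestSelection:
    def test_ar1_recovered(self, rng):
        resid = simulate_residuals("AR1", [1.0, 0.6], 200, 10, rng)
        fit = select_covariance(["VC", "AR1", "CS"], resid, np.arange(10.0), "AIC")
        assert fit.model.name == "AR1"
        assert abs(fit.theta[1] - 0.6) < 0.1

    def test_vc_preferred_on_iid(self):
        wins = 0
        reps = 60
        for s in range(reps):
            rng = np.random.default_rng(3000 + s)
            resid = rng.standard_normal((80, 5))
            fit = select_covariance(["VC", "AR1"], resid, np.arange(5.0), "AIC")
            wins += fit.model.name == "VC"
        assert wins >= int(0.9 * reps), wins

    def test_single_candidate(self, rng):
        resid = simulate_residuals("VC", [2.0], 100, 5, rng)
        fit = select_covariance(["VC"], resid, np.arange(5.0))
        assert fit.model.name == "VC"
        assert abs(fit.theta[0] - 2.0) < 0.3

    def test_mle_criterion_picks_max_loglik(self, rng):
        resid = simulate_residuals("AR1", [1.0, 0.5], 150, 6, rng)
        fit_aic = select_covariance(["VC", "AR1", "TOEP"], resid, np.arange(6.0), "AIC")
        fit_mle = select_covariance(["VC", "AR1", "TOEP"], resid, np.arange(6.0), "MLE")
        # MLE ignores parameter count, so it can only pick a model with
        # loglik >= the AIC choice's
        assert fit_mle.loglik >= fit_aic.loglik - 1e-6

    def test_nesting_never_decreases_loglik(self, rng):
        resid = simulate_residuals("CS", [1.0, 0.3], 120, 5, rng)
        ll_vc = fit_covariance_ml(get_covariance("VC"), resid).loglik
        ll_cs = fit_covariance_ml(get_covariance("CS"), resid).loglik
        ll_ar1 = fit_covariance_ml(get_covariance("AR1"), resid).loglik
        assert ll_cs >= ll_vc - 1e-6
        assert ll_ar1 >= ll_vc - 1e-6

    def test_aic_formula(self, rng):
        resid = simulate_residuals("AR1", [1.0, 0.4], 60, 4, rng)
        fit = fit_covariance_ml(get_covariance("AR1"), resid)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 2)

    def test_bad_criterion(self, rng):
        with pytest.raises(ValueError):
            select_covariance(["VC"], np.zeros((3, 2)), criterion="BIC")


class TestRegistry:
    def test_builtins(self):
        assert set(STRUCTURES) <= set(list_covariances())

    def test_duplicate_rejected(self):
        with pytest.raises(RegistryError):
            register_covariance(get_covariance("VC"))
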