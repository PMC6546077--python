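import dataclasses
import math

import numpy as np
import pytest

from longqtl import (
    CrossType,
    build_covariance,
    conditional_probs,
    fit_alternative,
    fit_null,
    genotype_density,
    get_covariance,
    get_curve,
    lr_statistic,
    mixture_loglik,
    mvn_logpdf,
    simulate_dataset,
)
from longqtl.genetics import ScanPosition, scan_grid
from longqtl.model import ConvergenceError, HypothesisFit
from tests.conftest import make_bc_config
from tests.oracles import naive_genotype_density, naive_mixture_loglik

CURVE = get_curve("logistic")
COV = get_covariance("AR1")


def qtl_marker_position(ds):
    """The scan position coinciding with the c1:15 marker is at 10 or 20; use
    the grid position nearest the fixture's true QTL."""
    grid = scan_grid(ds.gmap, 5.0)
    return min(grid, key=lambda p: abs(p.position - 15.0) + (p.chromosome != "c1") * 1e9)


class TestGenotypeDensity:
    def test_zero_quadratic_form(self):
        m = 6
        g = np.linspace(1, 5, m)
        got = genotype_density(g, None, None, g, np.eye(m))
        assert got == pytest.approx(-(m / 2) * math.log(2 * math.pi), abs=1e-12)

    def test_alpha_zero_equals_mvn(self, rng):
        m = 5
        y, g = rng.normal(size=m), rng.normal(size=m)
        sigma = build_covariance("AR1", [1.0, 0.4], m)
        got = genotype_density(y, np.array([1.0]), np.array([0.0]), g, sigma)
        assert got == pytest.approx(mvn_logpdf(y, g, sigma), abs=1e-12)

    def test_random_instance_vs_oracle(self, rng):
        for _ in range(25):
            m = 4
            A = rng.normal(size=(m, m))
            sigma = A @ A.T + m * np.eye(m)
            y, g = rng.normal(size=m), rng.normal(size=m)
            X_i, alpha = rng.normal(size=2), rng.normal(size=2)
            got = genotype_density(y, X_i, alpha, g, sigma)
            assert got == pytest.approx(naive_genotype_density(y, X_i, alpha, g, sigma), abs=1e-10)


class TestMixtureLoglik:
    def _tiny(self, rng, n=3, m=2, J=2):
        cfg = make_bc_config(n=n, seed=int(rng.integers(1e6)), times=np.arange(1.0, m + 1))
        ds, _ = simulate_dataset(cfg)
        probs = rng.dirichlet(np.ones(J), size=n)
        cp = np.vstack([[25 + 5 * j, 5.0, 0.5] for j in range(J)])
        theta = np.array([1.0, 0.3])
        return ds, probs, cp, theta

    def test_degenerate_mixture(self, rng):
        ds, _, cp, theta = self._tiny(rng)
        probs = np.tile([1.0, 0.0], (ds.n_individuals, 1))
        got = mixture_loglik(cp, np.zeros(0), theta, probs, ds, CURVE, COV)
        sigma = COV.build(theta, ds.pheno.n_times, ds.pheno.times)
        g1 = CURVE.value(cp[0], ds.pheno.times)
        expected = sum(mvn_logpdf(y, g1, sigma) for y in ds.pheno.values)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_label_invariance_identical_components(self, rng):
        ds, probs, cp, theta = self._tiny(rng)
        cp_same = np.vstack([cp[0], cp[0]])
        got = mixture_loglik(cp_same, np.zeros(0), theta, probs, ds, CURVE, COV)
        null_like = mixture_loglik(cp[:1], np.zeros(0), theta, np.ones((ds.n_individuals, 1)), ds, CURVE, COV)
        assert got == pytest.approx(null_like, abs=1e-10)

    def test_hand_sized_vs_naive_oracle(self, rng):
        for _ in range(10):
            ds, probs, cp, theta = self._tiny(rng)
            sigma = COV.build(theta, ds.pheno.n_times, ds.pheno.times)
            G = np.vstack([CURVE.value(p, ds.pheno.times) for p in cp])
            got = mixture_loglik(cp, np.zeros(0), theta, probs, ds, CURVE, COV)
            expected = naive_mixture_loglik(ds.pheno.values, probs, G, sigma)
            assert got == pytest.approx(expected, abs=1e-12 * max(1.0, abs(expected)))

    def test_individual_order_invariance(self, bc_dataset):
        ds, _ = bc_dataset
        perm = np.random.default_rng(0).permutation(ds.n_individuals)
        ds_perm = dataclasses.replace(
            ds,
            pheno=dataclasses.replace(
                ds.pheno,
                individual_ids=tuple(ds.pheno.individual_ids[i] for i in perm),
                values=ds.pheno.values[perm],
            ),
            geno=dataclasses.replace(
                ds.geno,
                individual_ids=tuple(ds.geno.individual_ids[i] for i in perm),
                codes=ds.geno.codes[perm],
            ),
        )
        cp = np.array([[30.0, 5.0, 0.5], [25.0, 5.0, 0.5]])
        theta = np.array([1.0, 0.6])
        pos = qtl_marker_position(ds)
        probs = conditional_probs(pos, ds.geno, ds.gmap, ds.cross)
        probs_perm = conditional_probs(pos, ds_perm.geno, ds_perm.gmap, ds_perm.cross)
        ll = mixture_loglik(cp, np.zeros(0), theta, probs, ds, CURVE, COV)
        ll_perm = mixture_loglik(cp, np.zeros(0), theta, probs_perm, ds_perm, CURVE, COV)
        assert ll == pytest.approx(ll_perm, abs=1e-10 * abs(ll))


class TestFitNull:
    def test_recovers_generating_params_without_qtl(self, null_dataset):
        ds, truth = null_dataset
        fit = fit_null(ds, CURVE, COV)
        a, b, r = fit.curve_params[0]
        assert a == pytest.approx(30.0, rel=0.1)
        assert r == pytest.approx(0.5, rel=0.25)
        assert fit.cov_theta[1] == pytest.approx(0.6, abs=0.15)
        assert fit.converged

    def test_deterministic(self, bc_dataset):
        ds, _ = bc_dataset
        f1 = fit_null(ds, CURVE, COV)
        f2 = fit_null(ds, CURVE, COV)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.curve_params, f2.curve_params)

    def test_single_individual_runs(self):
        cfg = make_bc_config(n=1, seed=9)
        ds, _ = simulate_dataset(cfg)
        fit = fit_null(ds, CURVE, COV)
        assert np.isfinite(fit.loglik)


class TestFitAlternative:
    def test_em_fixed_point_on_degenerate_probs(self, bc_dataset):
        ds, truth = bc_dataset
        hidden = np.asarray(truth["hidden_qtl_genotypes"])
        probs = np.eye(2)[hidden]
        h0 = fit_null(ds, CURVE, COV)
        h1 = fit_alternative(ds, probs, CURVE, COV, h0)
        # a second EM from the solution must not move the loglik
        h1b = fit_alternative(ds, probs, CURVE, COV, h1, max_iter=1)
        assert h1b.loglik == pytest.approx(h1.loglik, abs=1e-4)

    def test_loglik_never_below_init(self, bc_dataset):
        ds, _ = bc_dataset
        h0 = fit_null(ds, CURVE, COV)
        pos = qtl_marker_position(ds)
        probs = conditional_probs(pos, ds.geno, ds.gmap, ds.cross)
        h1 = fit_alternative(ds, probs, CURVE, COV, h0)
        assert h1.loglik >= h0.loglik - 1e-8
        assert h1.n_genotypes == 2

    def test_parameter_recovery_at_marker(self):
        cfg = make_bc_config(n=150, seed=42, n_chrom=1, qtl_pos=10.0)
        ds, truth = simulate_dataset(cfg)
        h0 = fit_null(ds, CURVE, COV)
        pos = ScanPosition("c1", 10.0, "m1_2", "m1_3")
        probs = conditional_probs(pos, ds.geno, ds.gmap, ds.cross)
        h1 = fit_alternative(ds, probs, CURVE, COV, h0)
        a_hat = sorted(h1.curve_params[:, 0])
        assert a_hat[0] == pytest.approx(25.0, rel=0.06)
        assert a_hat[1] == pytest.approx(30.0, rel=0.06)
        assert h1.cov_theta[1] == pytest.approx(0.6, abs=0.15)

    def test_bad_init_shape(self, bc_dataset):
        ds, _ = bc_dataset
        h0 = fit_null(ds, CURVE, COV)
        bad = dataclasses.replace(h0, curve_params=np.tile(h0.curve_params, (3, 1)))
        probs = np.full((ds.n_individuals, 2), 0.5)
        with pytest.raises(ValueError, match="curve rows"):
            fit_alternative(ds, probs, CURVE, COV, bad)


class TestLRStatistic:
    def _fit(self, ll):
        return HypothesisFit(np.zeros((1, 3)), np.zeros(2), np.zeros(0), ll, True, 1)

    def test_equal_fits_zero(self):
        assert lr_statistic(self._fit(-10.0), self._fit(-10.0)) == 0.0

    def test_positive(self):
        assert lr_statistic(self._fit(-12.0), self._fit(-10.0)) == pytest.approx(4.0)

    def test_small_negative_clipped(self):
        assert lr_statistic(self._fit(-10.0), self._fit(-10.0 - 1e-8)) == 0.0

    def test_large_negative_raises(self):
        with pytest.raises(ConvergenceError):
            lr_statistic(self._fit(-10.0), self._fit(-11.0))


class TestCovariates:
    def test_alpha_recovered(self):
        cfg = make_bc_config(n=150, seed=11, covariate_sd=2.0, covariate_alpha=1.5)
        ds, _ = simulate_dataset(cfg)
        fit = fit_null(ds, CURVE, COV)
        assert fit.alpha[0] == pytest.approx(1.5, abs=0.25)
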