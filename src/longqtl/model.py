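"""Functional-mapping likelihoods and their maximization.

The observation model: individual i with QTL genotype j has

    y_i ~ MVN( alpha X_i + g_j(times), Sigma(theta) ),

where g_j is a parametric mean curve per genotype, alpha a time-constant
covariate effect and Sigma a structured longitudinal covariance shared by
all genotypes.  The marginal (mixture) log-likelihood weights each genotype
by the conditional probability p_ij from the flanking markers; the null
model forces a single curve for all genotypes.  LR2 = -2 (loglik0 - loglik1)
is the scan statistic.

The alternative fit is a generalized EM.  The M-step is coordinate ascent
on the weighted complete-data log-likelihood, using its sufficient
statistics: each genotype's curve parameters solve a weighted least-squares
problem against the posterior-weighted mean trajectory in the Sigma^-1
metric, the covariate coefficient has a closed-form GLS update, and the
covariance parameters maximize -[N log det Sigma + tr(Sigma^-1 S)] with S
the weighted residual cross-product matrix.  Every sub-step starts from the
current value and cannot decrease the objective, so the observed
log-likelihood is monotone.  The null fit is the J=1 case of the same
routine.  Missing phenotype cells are handled throughout by grouping rows
by missingness pattern and marginalizing the MVN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.special import logsumexp

from ._optim import ParamTransform
from .covariance import CovarianceModel, mvn_logpdf, mvn_loglik_matrix
from .curves import CurveModel, fit_curve_ls
from .dataio import Dataset

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, fit: "HypothesisFit | None" = None):
        super().__init__(message)
        self.fit = fit


class MonotonicityError(RuntimeError):
    """EM observed log-likelihood decreased beyond tolerance (bug trap)."""


@dataclass(frozen=True)
class HypothesisFit:
    """MLE of one hypothesis: J curve-parameter rows (J=1 under the null)."""

    curve_params: np.ndarray  # (J, k)
    cov_theta: np.ndarray  # (p,)
    alpha: np.ndarray  # (c,), empty without covariates
    loglik: float
    converged: bool
    n_iter: int

    @property
    def n_genotypes(self) -> int:
        return self.curve_params.shape[0]


def _component_logdens(
    curve_params: np.ndarray,
    alpha: np.ndarray,
    theta: np.ndarray,
    ds: Dataset,
    curve: CurveModel,
    cov: CovarianceModel,
) -> np.ndarray:
    """n x J log f_j(y_i) under the given parameters."""
    times = ds.pheno.times
    m = len(times)
    G = np.vstack([curve.value(p, times) for p in np.atleast_2d(curve_params)])
    sigma = cov.build(theta, m, times)
    shift = None
    if np.size(alpha) and ds.pheno.covariates is not None:
        shift = ds.pheno.covariates @ alpha
    return mvn_loglik_matrix(ds.pheno.values, G, sigma, shift)


def genotype_density(
    y_i: np.ndarray,
    X_i: np.ndarray | None,
    alpha: np.ndarray | None,
    g_j: np.ndarray,
    sigma: np.ndarray,
) -> float:
    """log f_j(y_i): MVN log-density with mean alpha.X_i + g_j."""
    mean = np.asarray(g_j, dtype=float)
    if X_i is not None and alpha is not None and np.size(alpha):
        mean = mean + float(np.dot(np.atleast_1d(X_i), np.atleast_1d(alpha)))
    return mvn_logpdf(y_i, mean, sigma)


def mixture_loglik(
    curve_params: np.ndarray,
    alpha: np.ndarray,
    theta: np.ndarray,
    probs: np.ndarray,
    ds: Dataset,
    curve: CurveModel,
    cov: CovarianceModel,
) -> float:
    """sum_i log sum_j p_ij f_j(y_i), computed via log-sum-exp."""
    probs = np.asarray(probs, dtype=float)
    logf = _component_logdens(curve_params, alpha, theta, ds, curve, cov)
    if not np.all(np.isfinite(logf)):
        i, j = np.argwhere(~np.isfinite(logf))[0]
        raise FloatingPointError(f"non-finite component density for individual {ds.individual_ids[i]!r}, genotype {j}")
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    return float(np.sum(logsumexp(logp + logf, axis=1)))


class _Workspace:
    """Per-dataset precomputation: missingness patterns and covariates."""

    def __init__(self, ds: Dataset):
        self.ds = ds
        self.Y = ds.pheno.values
        self.times = ds.pheno.times
        self.m = len(self.times)
        self.X = ds.pheno.covariates
        self.n_covar = 0 if self.X is None else self.X.shape[1]
        finite = np.isfinite(self.Y)
        if finite.all():
            self.patterns = [(np.arange(self.Y.shape[0]), np.ones(self.m, dtype=bool))]
        else:
            masks, inverse = np.unique(finite, axis=0, return_inverse=True)
            self.patterns = [
                (np.flatnonzero(inverse == k), masks[k]) for k in range(masks.shape[0]) if masks[k].any()
            ]


def _nm_improve(fun, x0, bounds, maxiter):
    """Nelder-Mead in transformed space; never returns a worse point than x0
    (the start belongs to the initial simplex)."""
    tr = ParamTransform(bounds)
    z0 = tr.to_unconstrained(np.asarray(x0, dtype=float))

    def zfun(z):
        v = fun(tr.from_unconstrained(z))
        return v if np.isfinite(v) else 1e100

    f0 = zfun(z0)
    res = optimize.minimize(
        zfun, z0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8 * max(1.0, abs(f0))},
    )
    return tr.from_unconstrained(res.x) if res.fun <= f0 else np.asarray(x0, dtype=float)


def _gauss_newton_curve(curve, x0, times, stats, chol_p):
    """Weighted generalized-least-squares curve update via ``least_squares``
    with the curve's analytic gradient; falls back to the start on failure
    or non-improvement (preserving EM monotonicity)."""
    lo = np.array([b[0] for b in curve.param_bounds()])
    hi = np.array([b[1] for b in curve.param_bounds()])
    eps = 1e-12

    def resid(params):
        g = curve.value(params, times)
        parts = [np.sqrt(Wj) * (U.T @ (ybar - g[obs])) for Wj, ybar, obs, _, k_p in stats for U in (chol_p[k_p],)]
        return np.concatenate(parts)

    def jac(params):
        dg = curve.grad(params, times)  # (k, m)
        parts = [-np.sqrt(Wj) * (chol_p[k_p].T @ dg[:, obs].T) for Wj, ybar, obs, _, k_p in stats]
        return np.concatenate(parts, axis=0)

    x0c = np.clip(x0, lo + eps, hi - eps)
    try:
        res = optimize.least_squares(
            resid, x0c, jac=jac, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=None, max_nfev=60,
        )
    except Exception:
        return np.asarray(x0, dtype=float)
    f0 = float(np.sum(resid(x0c) ** 2))
    return res.x if res.cost * 2 <= f0 else np.asarray(x0, dtype=float)


def _mstep(
    ws: _Workspace,
    curve: CurveModel,
    cov: CovarianceModel,
    w: np.ndarray,  # (n, J) posterior weights
    cp: np.ndarray,  # (J, k) current curve params
    alpha: np.ndarray,
    theta: np.ndarray,
    curve_maxiter: int = 120,
    cov_maxiter: int = 80,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One coordinate-ascent cycle over (curves | alpha | theta)."""
    J = w.shape[1]
    times, m = ws.times, ws.m

    sigma = cov.build(theta, m, times)
    # per-pattern inverse of the observed-coordinate covariance
    inv_p = [linalg.inv(sigma[np.ix_(obs, obs)]) for _, obs in ws.patterns]

    shift = ws.X @ alpha if ws.n_covar else None
    Yadj = ws.Y if shift is None else ws.Y - shift[:, None]

    # --- curve parameters: weighted mean trajectory per genotype & pattern
    # whitening factors for the Gauss-Newton path: A = U U^T
    curve_grad = getattr(curve, "grad", None)
    chol_p = [np.linalg.cholesky(A) for A in inv_p] if curve_grad is not None else None
    cp = cp.copy()
    for j in range(J):
        stats = []
        for k_p, ((rows, obs), A) in enumerate(zip(ws.patterns, inv_p)):
            wj = w[rows, j]
            Wj = float(wj.sum())
            if Wj <= 1e-12:
                continue
            ybar = (wj @ Yadj[np.ix_(rows, np.flatnonzero(obs))]) / Wj
            stats.append((Wj, ybar, obs, A, k_p))
        if not stats:
            continue

        if curve_grad is not None:
            cp[j] = _gauss_newton_curve(curve, cp[j], times, stats, chol_p)
            continue

        def curve_obj(params, stats=stats):
            g = curve.value(params, times)
            if not np.all(np.isfinite(g)):
                return np.inf
            tot = 0.0
            for Wj, ybar, obs, A, _ in stats:
                d = ybar - g[obs]
                tot += Wj * float(d @ A @ d)
            return tot

        cp[j] = _nm_improve(curve_obj, cp[j], curve.param_bounds(), curve_maxiter)

    G = np.vstack([curve.value(p, times) for p in cp])

    # --- covariate coefficients: closed-form GLS (exact maximizer)
    if ws.n_covar:
        M = np.zeros((ws.n_covar, ws.n_covar))
        v = np.zeros(ws.n_covar)
        for (rows, obs), A in zip(ws.patterns, inv_p):
            one_A = A.sum(axis=0)  # 1' Sigma^-1
            s11 = float(one_A.sum())  # 1' Sigma^-1 1
            Xp = ws.X[rows]
            wrow = w[rows].sum(axis=1)  # == 1
            M += s11 * (Xp.T * wrow) @ Xp
            D = ws.Y[np.ix_(rows, np.flatnonzero(obs))]
            for j in range(J):
                proj = (D - G[j][obs]) @ one_A  # 1'A(y_i - g_j)
                v += ((w[rows, j] * proj)[None, :] @ Xp).ravel()
        try:
            alpha = np.linalg.solve(M, v)
        except np.linalg.LinAlgError:
            pass
        shift = ws.X @ alpha
        Yadj = ws.Y - shift[:, None]

    # --- covariance parameters: weighted residual cross-products
    pattern_stats = []
    for (rows, obs), _ in zip(ws.patterns, inv_p):
        D = Yadj[np.ix_(rows, np.flatnonzero(obs))]
        S = np.zeros((int(obs.sum()),) * 2)
        for j in range(J):
            R = D - G[j][obs]
            S += (R * w[rows, j][:, None]).T @ R
        pattern_stats.append((float(w[rows].sum()), obs, S))

    def _neg2ll_parts(sig):
        """(sum_p N_p logdet_p, sum_p trace(Sigma_p^-1 S_p), sum_p N_p m_p)."""
        logdet_tot = tr_tot = dof = 0.0
        for N_p, obs, S in pattern_stats:
            sub = sig[np.ix_(obs, obs)]
            L = linalg.cholesky(sub, lower=True)
            logdet_tot += N_p * 2.0 * np.sum(np.log(np.diag(L)))
            tr_tot += np.trace(linalg.cho_solve((L, True), S))
            dof += N_p * len(S)
        return logdet_tot, tr_tot, dof

    def cov_obj(th):
        try:
            sig = cov.build(th, m, times)
            logdet, tr, _ = _neg2ll_parts(sig)
        except (ValueError, linalg.LinAlgError):
            return np.inf
        return 0.5 * (logdet + tr)

    bounds = cov.param_bounds(m)
    si = getattr(cov, "scale_index", None)
    if si == 0:
        # Sigma = s * C(rest): the ML scale given rest is closed-form
        s_lo, s_hi = bounds[0]
        rest_bounds = bounds[1:]

        def with_scale(rest):
            try:
                C = cov.build(np.concatenate([[1.0], rest]), m, times)
                logdetC, trC, dof = _neg2ll_parts(C)
            except (ValueError, linalg.LinAlgError):
                return None, np.inf
            s_hat = float(np.clip(trC / max(dof, 1.0), s_lo, min(s_hi, 1e300)))
            return s_hat, 0.5 * (logdetC + dof * np.log(s_hat) + trC / s_hat)

        if rest_bounds:
            rest0 = theta[1:]
            rest = _nm_improve(lambda r: with_scale(r)[1], rest0, rest_bounds, cov_maxiter)
        else:
            rest = theta[1:]
        s_hat, val = with_scale(rest)
        if s_hat is not None:
            theta_new = np.concatenate([[s_hat], rest])
            if val <= cov_obj(theta):
                return cp, alpha, theta_new
        return cp, alpha, theta

    theta = _nm_improve(cov_obj, theta, bounds, cov_maxiter)
    return cp, alpha, theta


def _run_em(
    ds: Dataset,
    probs: np.ndarray,
    curve: CurveModel,
    cov: CovarianceModel,
    cp: np.ndarray,
    alpha: np.ndarray,
    theta: np.ndarray,
    tol: float,
    max_iter: int,
) -> HypothesisFit:
    ws = _Workspace(ds)
    probs = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)

    def observed_ll(logf):
        if not np.all(np.isfinite(logf)):
            i, j = np.argwhere(~np.isfinite(logf))[0]
            raise FloatingPointError(
                f"non-finite component density for individual {ds.individual_ids[i]!r}, genotype {j}"
            )
        return float(np.sum(logsumexp(logp + logf, axis=1)))

    logf = _component_logdens(cp, alpha, theta, ds, curve, cov)
    ll = observed_ll(logf)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logw = logp + logf
        logw -= logsumexp(logw, axis=1, keepdims=True)
        w = np.exp(logw)
        cp, alpha, theta = _mstep(ws, curve, cov, w, cp, alpha, theta)
        logf = _component_logdens(cp, alpha, theta, ds, curve, cov)
        ll_new = observed_ll(logf)
        if ll_new < ll - 1e-8 * max(1.0, abs(ll)):
            raise MonotonicityError(f"EM log-likelihood decreased: {ll} -> {ll_new}")
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return HypothesisFit(cp, theta, alpha, float(ll), converged, it)


def fit_null(
    ds: Dataset,
    curve: CurveModel,
    cov: CovarianceModel,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> HypothesisFit:
    """MLE of the single-curve (no-QTL) model; position-independent.

    Runs the same coordinate-ascent machinery as the alternative fit with a
    degenerate one-component mixture, initialized from an unweighted
    least-squares curve fit and the covariance model's moment-based guess.
    """
    times = ds.pheno.times
    Y = ds.pheno.values
    ls = fit_curve_ls(curve, times, Y)
    resid = Y - curve.value(ls.params, times)
    n_covar = 0 if ds.pheno.covariates is None else ds.pheno.covariates.shape[1]
    alpha0 = np.zeros(n_covar)
    theta0 = cov.initial_guess(resid, times)
    probs = np.ones((ds.n_individuals, 1))
    fit = _run_em(ds, probs, curve, cov, np.atleast_2d(ls.params), alpha0, theta0, tol, max_iter)
    if not np.isfinite(fit.loglik):
        raise ConvergenceError("null fit produced non-finite log-likelihood", fit)
    if not fit.converged:
        raise ConvergenceError(f"null fit did not converge in {max_iter} iterations", fit)
    return fit


def fit_alternative(
    ds: Dataset,
    probs: np.ndarray,
    curve: CurveModel,
    cov: CovarianceModel,
    init: HypothesisFit,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> HypothesisFit:
    """Generalized EM for the genotype-mixture model.

    ``init`` is either a null fit (curve parameters are replicated per
    genotype and perturbed by +/-1% to break symmetry) or a previous
    alternative fit (warm start).
    """
    J = np.asarray(probs).shape[1]
    n_covar = 0 if ds.pheno.covariates is None else ds.pheno.covariates.shape[1]

    cp = np.atleast_2d(np.asarray(init.curve_params, dtype=float))
    from_null = cp.shape[0] == 1 and J > 1
    if from_null:
        cp = np.vstack([cp[0] * (1.0 + 0.01 * (-1) ** j) for j in range(J)])
    elif cp.shape[0] != J:
        raise ValueError(f"init has {cp.shape[0]} curve rows; expected 1 or {J}")
    alpha = np.asarray(init.alpha, dtype=float)
    if alpha.size != n_covar:
        alpha = np.zeros(n_covar)
    theta = np.asarray(init.cov_theta, dtype=float)

    fit = _run_em(ds, probs, curve, cov, cp, alpha, theta, tol, max_iter)
    if from_null and fit.loglik < init.loglik:
        # the symmetry-breaking perturbation can strand EM fractionally below
        # the null optimum on QTL-free positions; the exact replicated start
        # (whose mixture loglik equals the null loglik) recovers it
        cp0 = np.repeat(np.atleast_2d(init.curve_params), J, axis=0)
        refit = _run_em(ds, probs, curve, cov, cp0, alpha, np.asarray(init.cov_theta, dtype=float), tol, max_iter)
        if refit.loglik > fit.loglik:
            fit = refit
    return fit


def lr_statistic(h0: HypothesisFit, h1: HypothesisFit, tol: float = 1e-6) -> float:
    """LR2 = -2 (loglik0 - loglik1); small negatives clip to 0, larger ones
    indicate an optimizer failure and raise."""
    lr2 = -2.0 * (h0.loglik - h1.loglik)
    if lr2 < -tol:
        raise ConvergenceError(f"negative LR2 ({lr2:.3g}): alternative fit worse than null", h1)
    return max(lr2, 0.0)
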