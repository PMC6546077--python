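"""Structured longitudinal covariance models Sigma(theta) and their
Gaussian log-likelihoods.

Built-ins: VC (diagonal), CS (compound symmetry), AR1 (index-lag
autoregressive), AR1_time (calendar-time lag), ARMA11, Toeplitz (free lags
via partial autocorrelations, so every in-bounds parameter vector is
positive-definite) and SAD1 (first-order ante-dependence).

Every parameter vector stores variances on the natural scale; optimization
happens in an unconstrained space (log for variances, atanh for
correlations) through :mod:`longqtl._optim`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._optim import minimize_bounded

_VAR_BOUNDS = (1e-14, np.inf)
_CORR_BOUNDS = (-0.999, 0.999)


class RegistryError(ValueError):
    pass


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


class CovarianceModel:
    """Contract for a structured m x m covariance family."""

    name: str = ""
    # index of a pure scale parameter (Sigma is linear in it), or None;
    # lets likelihood code profile the scale out analytically
    scale_index: int | None = 0

    def n_params(self, m: int) -> int:
        raise NotImplementedError

    def build(self, theta: np.ndarray, m: int, times: np.ndarray | None = None) -> np.ndarray:
        raise NotImplementedError

    def param_bounds(self, m: int) -> list[tuple[float, float]]:
        raise NotImplementedError

    def initial_guess(self, residuals: np.ndarray, times: np.ndarray | None = None) -> np.ndarray:
        raise NotImplementedError

    def _check(self, theta: np.ndarray, m: int) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params(m),):
            raise ValueError(f"{self.name}: expected {self.n_params(m)} parameters, got {theta.shape}")
        for v, (lo, hi) in zip(theta, self.param_bounds(m)):
            if not (lo <= v <= hi):
                raise ValueError(f"{self.name}: parameter {v} outside [{lo}, {hi}]")
        return theta


def _sample_moments(residuals: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-time variances and pooled lag-1 autocorrelation of residual rows."""
    var_t = np.nanvar(residuals, axis=0)
    var_t = np.clip(var_t, 1e-8, None)
    m = residuals.shape[1]
    num = den = 0.0
    for t in range(m - 1):
        a, b = residuals[:, t], residuals[:, t + 1]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() > 2:
            num += np.cov(a[ok], b[ok])[0, 1]
            den += np.sqrt(var_t[t] * var_t[t + 1])
    rho1 = float(np.clip(num / den if den > 0 else 0.0, -0.95, 0.95))
    return var_t, rho1


class VarianceComponents(CovarianceModel):
    """sigma^2 I."""

    name = "VC"

    def n_params(self, m):
        return 1

    def build(self, theta, m, times=None):
        (s2,) = self._check(theta, m)
        return s2 * np.eye(m)

    def param_bounds(self, m):
        return [_VAR_BOUNDS]

    def initial_guess(self, residuals, times=None):
        return np.array([float(np.nanvar(residuals))])


class CompoundSymmetry(CovarianceModel):
    """sigma^2 [(1-rho) I + rho J]; rho bounded inside (-1/(m-1), 1)."""

    name = "CS"

    def n_params(self, m):
        return 2

    def build(self, theta, m, times=None):
        s2, rho = self._check(theta, m)
        return s2 * ((1.0 - rho) * np.eye(m) + rho * np.ones((m, m)))

    def param_bounds(self, m):
        lo = -1.0 / max(m - 1, 1) + 1e-6
        return [_VAR_BOUNDS, (lo, 0.999)]

    def initial_guess(self, residuals, times=None):
        var_t, rho1 = _sample_moments(residuals)
        m = residuals.shape[1]
        lo = -1.0 / max(m - 1, 1) + 1e-5
        return np.array([float(np.mean(var_t)), np.clip(rho1, lo, 0.95)])


class AR1(CovarianceModel):
    """sigma^2 rho^|s-t| on index distance (equally spaced measurements)."""

    name = "AR1"

    def n_params(self, m):
        return 2

    def _lags(self, m, times):
        idx = np.arange(m)
        return np.abs(idx[:, None] - idx[None, :]).astype(float)

    def build(self, theta, m, times=None):
        s2, rho = self._check(theta, m)
        return s2 * rho ** self._lags(m, times)

    def param_bounds(self, m):
        return [_VAR_BOUNDS, _CORR_BOUNDS]

    def initial_guess(self, residuals, times=None):
        var_t, rho1 = _sample_moments(residuals)
        return np.array([float(np.mean(var_t)), rho1])


class AR1Time(AR1):
    """AR(1) with calendar-time distance |t_s - t_t| as the exponent."""

    name = "AR1_time"

    def _lags(self, m, times):
        if times is None:
            return super()._lags(m, None)
        t = np.asarray(times, dtype=float)
        return np.abs(t[:, None] - t[None, :])

    def param_bounds(self, m):
        return [_VAR_BOUNDS, (1e-6, 0.999)]  # negative rho undefined for real lags

    def initial_guess(self, residuals, times=None):
        var_t, rho1 = _sample_moments(residuals)
        return np.array([float(np.mean(var_t)), float(np.clip(abs(rho1), 1e-3, 0.95))])


def arma11_acf_coeffs(phi: float, psi: float) -> tuple[float, float]:
    """(gamma, rho) of the lag correlation gamma * rho^(k-1) for ARMA(1,1)
    with AR coefficient phi and MA coefficient psi."""
    denom = 1.0 + 2.0 * phi * psi + psi * psi
    gamma = (1.0 + phi * psi) * (phi + psi) / denom
    return gamma, phi


class ARMA11(CovarianceModel):
    """Diagonal sigma^2; off-diagonal sigma^2 * gamma * rho^(|s-t|-1).

    Parameterized by the process coefficients (sigma^2, phi, psi) so that
    every in-bounds theta yields a valid (positive-definite) autocorrelation;
    (gamma, rho) follow from (phi, psi).
    """

    name = "ARMA11"

    def n_params(self, m):
        return 3

    def build(self, theta, m, times=None):
        s2, phi, psi = self._check(theta, m)
        gamma, rho = arma11_acf_coeffs(phi, psi)
        lag = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
        # integer exponents, so negative rho is well defined
        corr = np.where(lag == 0, 1.0, gamma * np.power(float(rho), np.clip(lag - 1, 0, None).astype(float)))
        return s2 * corr

    def param_bounds(self, m):
        return [_VAR_BOUNDS, _CORR_BOUNDS, _CORR_BOUNDS]

    def initial_guess(self, residuals, times=None):
        var_t, rho1 = _sample_moments(residuals)
        return np.array([float(np.mean(var_t)), rho1, 0.0])


def pacf_to_acf(pacf: np.ndarray) -> np.ndarray:
    """Durbin-Levinson: partial autocorrelations (each in (-1,1)) to the
    autocorrelation sequence rho_1..rho_K of a valid stationary process."""
    pacf = np.asarray(pacf, dtype=float)
    K = len(pacf)
    acf = np.zeros(K)
    phi_prev = np.zeros(0)
    for k in range(1, K + 1):
        pk = pacf[k - 1]
        if k == 1:
            acf[0] = pk
            phi = np.array([pk])
        else:
            prev_acf = acf[: k - 1]
            acf[k - 1] = phi_prev @ prev_acf[::-1] + pk * (1.0 - phi_prev @ prev_acf)
            phi = np.concatenate([phi_prev - pk * phi_prev[::-1], [pk]])
        phi_prev = phi
    return acf


class ToeplitzBanded(CovarianceModel):
    """Toeplitz with free lag correlations, parameterized through partial
    autocorrelations so positive-definiteness holds across the bounds."""

    name = "TOEP"

    def n_params(self, m):
        return m  # sigma^2 + (m-1) partial autocorrelations

    def build(self, theta, m, times=None):
        theta = self._check(theta, m)
        s2, pacf = theta[0], theta[1:]
        acf = np.concatenate([[1.0], pacf_to_acf(pacf)]) if m > 1 else np.array([1.0])
        return s2 * linalg.toeplitz(acf)

    def param_bounds(self, m):
        return [_VAR_BOUNDS] + [_CORR_BOUNDS] * (m - 1)

    def initial_guess(self, residuals, times=None):
        var_t, rho1 = _sample_moments(residuals)
        m = residuals.shape[1]
        pacf = np.zeros(m - 1)
        if m > 1:
            pacf[0] = rho1
        return np.concatenate([[float(np.mean(var_t))], pacf])


class SAD1(CovarianceModel):
    """First-order structured ante-dependence: y_t = phi_t y_{t-1} + e_t.

    theta = (v_1..v_m innovation variances, phi_2..phi_m lag coefficients);
    Sigma follows the recursion Sigma[t,t] = phi_t^2 Sigma[t-1,t-1] + v_t and
    Sigma[s,t] = (prod_{k=s+1..t} phi_k) Sigma[s,s] for s < t.
    """

    name = "SAD1"
    scale_index = None  # innovation variances enter nonlinearly

    def n_params(self, m):
        return 2 * m - 1

    def build(self, theta, m, times=None):
        theta = self._check(theta, m)
        v, phi = theta[:m], theta[m:]
        S = np.zeros((m, m))
        S[0, 0] = v[0]
        for t in range(1, m):
            S[t, t] = phi[t - 1] ** 2 * S[t - 1, t - 1] + v[t]
        for s in range(m):
            acc = S[s, s]
            for t in range(s + 1, m):
                acc *= phi[t - 1]
                S[s, t] = S[t, s] = acc
        return S

    def param_bounds(self, m):
        return [_VAR_BOUNDS] * m + [(-10.0, 10.0)] * (m - 1)

    def initial_guess(self, residuals, times=None):
        m = residuals.shape[1]
        var_t, _ = _sample_moments(residuals)
        phi = np.zeros(m - 1)
        v = var_t.copy()
        for t in range(1, m):
            a, b = residuals[:, t - 1], residuals[:, t]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() > 2:
                phi[t - 1] = float(np.clip(np.cov(a[ok], b[ok])[0, 1] / var_t[t - 1], -5, 5))
            v[t] = max(var_t[t] - phi[t - 1] ** 2 * var_t[t - 1], 1e-6)
        return np.concatenate([v, phi])


_REGISTRY: dict[str, CovarianceModel] = {}


def register_covariance(model: CovarianceModel, overwrite: bool = False) -> None:
    if not model.name:
        raise RegistryError("covariance model must have a name")
    if model.name in _REGISTRY and not overwrite:
        raise RegistryError(f"covariance {model.name!r} already registered")
    _REGISTRY[model.name] = model


def get_covariance(name: str) -> CovarianceModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise RegistryError(f"unknown covariance {name!r}; registered: {sorted(_REGISTRY)}") from None


def list_covariances() -> list[str]:
    return list(_REGISTRY)


for _m in (VarianceComponents(), CompoundSymmetry(), AR1(), AR1Time(), ARMA11(), ToeplitzBanded(), SAD1()):
    register_covariance(_m, overwrite=True)


def build_covariance(name: str, theta: np.ndarray, m: int, times: np.ndarray | None = None) -> np.ndarray:
    return get_covariance(name).build(theta, m, times)


def _chol(sigma: np.ndarray, who: str = "") -> np.ndarray:
    try:
        return linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(f"covariance not positive-definite {who}".strip()) from exc


def mvn_logpdf(y: np.ndarray, mean: np.ndarray, sigma: np.ndarray) -> float:
    """Gaussian log-density of one observation; NaN coordinates are
    marginalized out (density of the observed sub-vector)."""
    y = np.asarray(y, dtype=float)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), y.shape)
    obs = np.isfinite(y)
    if not obs.any():
        return 0.0
    yo = y[obs] - mean[obs]
    so = np.asarray(sigma)[np.ix_(obs, obs)]
    L = _chol(so)
    z = linalg.solve_triangular(L, yo, lower=True)
    k = int(obs.sum())
    return float(-0.5 * (k * np.log(2.0 * np.pi) + 2.0 * np.sum(np.log(np.diag(L))) + z @ z))


def mvn_loglik_matrix(
    Y: np.ndarray,
    means: np.ndarray,
    sigma: np.ndarray,
    shift: np.ndarray | None = None,
) -> np.ndarray:
    """n x J matrix of log N(y_i; shift_i + means_j, Sigma).

    Rows with missing cells are grouped by missingness pattern and evaluated
    on the observed coordinates only.  This is the package's hot loop.
    """
    Y = np.asarray(Y, dtype=float)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    n, m = Y.shape
    J = means.shape[0]
    if shift is not None:
        Y = Y - np.asarray(shift, dtype=float)[:, None]
    out = np.empty((n, J))
    finite = np.isfinite(Y)
    if finite.all():
        L = _chol(sigma)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        const = -0.5 * (m * np.log(2.0 * np.pi) + logdet)
        for j in range(J):
            Z = linalg.solve_triangular(L, (Y - means[j]).T, lower=True)
            out[:, j] = const - 0.5 * np.einsum("ij,ij->j", Z, Z)
        return out
    patterns, inverse = np.unique(finite, axis=0, return_inverse=True)
    for p_idx in range(patterns.shape[0]):
        rows = np.flatnonzero(inverse == p_idx)
        obs = patterns[p_idx]
        k = int(obs.sum())
        if k == 0:
            out[rows] = 0.0
            continue
        so = sigma[np.ix_(obs, obs)]
        L = _chol(so, f"(individuals {rows[:3]}...)")
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        const = -0.5 * (k * np.log(2.0 * np.pi) + logdet)
        Ysub = Y[np.ix_(rows, np.flatnonzero(obs))]
        for j in range(J):
            Z = linalg.solve_triangular(L, (Ysub - means[j][obs]).T, lower=True)
            out[rows, j] = const - 0.5 * np.einsum("ij,ij->j", Z, Z)
    return out


@dataclass(frozen=True)
class CovarianceFit:
    model: CovarianceModel
    theta: np.ndarray
    loglik: float
    aic: float


def fit_covariance_ml(
    model: CovarianceModel,
    residuals: np.ndarray,
    times: np.ndarray | None = None,
    maxiter: int = 400,
) -> CovarianceFit:
    """Maximum-likelihood theta for centered residual rows under one model."""
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    m = residuals.shape[1]
    zero = np.zeros(m)

    def nll(theta):
        try:
            sig = model.build(theta, m, times)
            return -float(np.sum(mvn_loglik_matrix(residuals, zero, sig)))
        except (NotPositiveDefiniteError, ValueError):
            return np.inf

    x0 = model.initial_guess(residuals, times)
    res = minimize_bounded(nll, x0, model.param_bounds(m), method="Nelder-Mead", maxiter=maxiter)
    theta = res.x
    ll = -float(res.fun)
    k = model.n_params(m)
    return CovarianceFit(model, theta, ll, -2.0 * ll + 2.0 * k)


def select_covariance(
    candidates: list[CovarianceModel] | list[str],
    residuals: np.ndarray,
    times: np.ndarray | None = None,
    criterion: str = "AIC",
) -> CovarianceFit:
    """ML-fit every candidate and pick by AIC (or raw loglik when
    criterion='MLE'; beware overfitting).  Ties break toward fewer
    parameters, then candidate order."""
    crit = criterion.upper()
    if crit not in ("AIC", "MLE"):
        raise ValueError("criterion must be 'AIC' or 'MLE'")
    if not candidates:
        raise ValueError("need at least one candidate covariance")
    models = [get_covariance(c) if isinstance(c, str) else c for c in candidates]
    m = np.atleast_2d(residuals).shape[1]
    scored = []
    errors = []
    for rank, mod in enumerate(models):
        try:
            fit = fit_covariance_ml(mod, residuals, times)
        except Exception as exc:
            errors.append(f"{mod.name}: {exc}")
            continue
        key = fit.aic if crit == "AIC" else -fit.loglik
        scored.append((round(key, 9), mod.n_params(m), rank, fit))
    if not scored:
        raise RuntimeError("all covariance fits failed: " + "; ".join(errors))
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]
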