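"""Parametric mean-trajectory families, least-squares fitting and
information-criterion selection.

The registry ships four built-ins (logistic, double-logistic, Legendre,
pharmacology) and accepts user-defined curves at run time.  AIC/BIC use the
Gaussian concentrated least-squares form so that curve selection does not
require a covariance model:

    AIC = N log(RSS/N) + 2k,   BIC = N log(RSS/N) + k log N,

with N the number of observed phenotype cells and k the parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import optimize, stats

from ._optim import ParamTransform


class RegistryError(ValueError):
    pass


class FitError(RuntimeError):
    def __init__(self, message: str, best: "CurveFit | None" = None):
        super().__init__(message)
        self.best = best


class CurveModel:
    """Contract for a mean-trajectory family g(params, t)."""

    name: str = ""
    n_params: int = 0

    def value(self, params: np.ndarray, times: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_bounds(self) -> list[tuple[float, float]]:
        raise NotImplementedError

    def initial_guess(self, times: np.ndarray, y_mean: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class LogisticCurve(CurveModel):
    """g(t) = a / (1 + b e^(-r t)); a the asymptote, r the growth rate."""

    name = "logistic"
    n_params = 3

    def value(self, params, times):
        a, b, r = params
        return a / (1.0 + b * np.exp(-r * np.asarray(times, dtype=float)))

    def grad(self, params, times):
        """(n_params, m) partial derivatives of the curve value."""
        a, b, r = params
        t = np.asarray(times, dtype=float)
        e = np.exp(-r * t)
        denom = 1.0 + b * e
        return np.vstack([1.0 / denom, -a * e / denom**2, a * b * t * e / denom**2])

    def param_bounds(self):
        return [(-np.inf, np.inf), (1e-9, np.inf), (1e-6, 50.0)]

    def initial_guess(self, times, y_mean):
        a = float(np.nanmax(y_mean)) * 1.05
        if a <= 0:
            a = 1.0
        y0 = float(y_mean[0]) if np.isfinite(y_mean[0]) and y_mean[0] > 0 else a / 10.0
        b = max(a / y0 - 1.0, 1e-3)
        # log-linear regression on the logit-transformed trajectory
        with np.errstate(all="ignore"):
            z = np.log(np.clip(a / np.clip(y_mean, 1e-12, None) - 1.0, 1e-9, None))
        ok = np.isfinite(z)
        if ok.sum() >= 2 and np.ptp(times[ok]) > 0:
            r = -float(stats.linregress(times[ok], z[ok]).slope)
        else:
            r = 0.5
        r = float(np.clip(r, 1e-3, 10.0))
        return np.array([a, b, r])


def logistic_value(a: float, b: float, r: float, t: float | np.ndarray) -> float | np.ndarray:
    """Convenience scalar/vector evaluation of the logistic curve."""
    denom = 1.0 + b * np.exp(-r * np.asarray(t, dtype=float))
    if np.any(denom == 0):
        raise FloatingPointError("logistic denominator is zero")
    out = a / denom
    return float(out) if out.ndim == 0 else out


class DoubleLogisticCurve(CurveModel):
    """Sum of two logistic components (composite growth)."""

    name = "double_logistic"
    n_params = 6

    def value(self, params, times):
        a1, b1, r1, a2, b2, r2 = params
        t = np.asarray(times, dtype=float)
        return a1 / (1.0 + b1 * np.exp(-r1 * t)) + a2 / (1.0 + b2 * np.exp(-r2 * t))

    def param_bounds(self):
        return [(-np.inf, np.inf), (1e-9, np.inf), (1e-6, 50.0)] * 2

    def initial_guess(self, times, y_mean):
        base = LogisticCurve().initial_guess(times, y_mean)
        half = base.copy()
        half[0] *= 0.5
        return np.concatenate([half, half * np.array([1.0, 1.5, 0.6])])


class LegendreCurve(CurveModel):
    """Legendre-polynomial trajectory on times rescaled to [-1, 1].

    Rescaling uses the min/max of the times supplied to ``value``; fits and
    predictions therefore share a domain whenever they share the time span.
    """

    def __init__(self, order: int = 4):
        self.order = int(order)
        self.name = f"legendre{self.order}"
        self.n_params = self.order + 1

    def _rescale(self, times):
        t = np.asarray(times, dtype=float)
        lo, hi = t.min(), t.max()
        if hi == lo:
            return np.zeros_like(t)
        return 2.0 * (t - lo) / (hi - lo) - 1.0

    def value(self, params, times):
        return npleg.legval(self._rescale(times), np.asarray(params, dtype=float))

    def design_matrix(self, times):
        """Linear-in-parameters: columns are Legendre basis polynomials."""
        x = self._rescale(times)
        return npleg.legvander(x, self.order)

    def param_bounds(self):
        return [(-np.inf, np.inf)] * self.n_params

    def initial_guess(self, times, y_mean):
        x = self._rescale(times)
        ok = np.isfinite(y_mean)
        deg = min(self.order, max(int(ok.sum()) - 1, 0))
        coef = npleg.legfit(x[ok], y_mean[ok], deg)
        return np.concatenate([coef, np.zeros(self.n_params - len(coef))])


class PharmacologyCurve(CurveModel):
    """Emax dose/time-response: E(t) = E0 + Emax * t / (E50 + t)."""

    name = "pharmacology"
    n_params = 3

    def value(self, params, times):
        e0, emax, e50 = params
        t = np.asarray(times, dtype=float)
        return e0 + emax * t / (e50 + t)

    def grad(self, params, times):
        e0, emax, e50 = params
        t = np.asarray(times, dtype=float)
        return np.vstack([np.ones_like(t), t / (e50 + t), -emax * t / (e50 + t) ** 2])

    def param_bounds(self):
        return [(-np.inf, np.inf), (-np.inf, np.inf), (1e-6, np.inf)]

    def initial_guess(self, times, y_mean):
        e0 = float(y_mean[0])
        emax = float(np.nanmax(y_mean) - e0)
        if emax == 0:
            emax = 1.0
        e50 = float(np.median(times))
        return np.array([e0, emax, max(e50, 1e-3)])


_REGISTRY: dict[str, CurveModel] = {}


def register_curve(model: CurveModel, overwrite: bool = False) -> None:
    if not model.name:
        raise RegistryError("curve model must have a name")
    if model.name in _REGISTRY and not overwrite:
        raise RegistryError(f"curve {model.name!r} already registered")
    _REGISTRY[model.name] = model


def get_curve(name: str) -> CurveModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise RegistryError(f"unknown curve {name!r}; registered: {sorted(_REGISTRY)}") from None


def list_curves() -> list[str]:
    return list(_REGISTRY)


def _install_builtins() -> None:
    for m in (LogisticCurve(), DoubleLogisticCurve(), LegendreCurve(4), PharmacologyCurve()):
        register_curve(m, overwrite=True)


_install_builtins()


@dataclass(frozen=True)
class CurveFit:
    model: CurveModel
    params: np.ndarray
    rss: float
    aic: float
    bic: float
    n_obs: int


def _rss(model: CurveModel, params: np.ndarray, times: np.ndarray, values: np.ndarray) -> float:
    pred = model.value(params, times)
    resid = values - pred  # broadcasts over rows
    return float(np.nansum(resid * resid))


def _rss_parts(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Decompose the all-rows RSS: sum_it (y_it - g_t)^2 =
    sum_t w_t (ybar_t - g_t)^2 + within-time scatter (constant in g)."""
    w = np.isfinite(values).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        ybar = np.where(w > 0, np.nansum(values, axis=0) / np.maximum(w, 1.0), 0.0)
    within = float(np.nansum((values - ybar) ** 2))
    return w, ybar, within


def fit_curve_ls(
    model: CurveModel,
    times: np.ndarray,
    values: np.ndarray,
    restarts: int = 5,
    seed: int = 0,
) -> CurveFit:
    """Least-squares fit of one mean curve to all rows of ``values``.

    Derivative-free simplex with jittered restarts; missing cells are simply
    excluded from the RSS.
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if times.size < model.n_params:
        raise FitError(f"{model.name}: need at least {model.n_params} time points")
    y_mean = np.nanmean(values, axis=0)
    x0 = np.asarray(model.initial_guess(times, y_mean), dtype=float)
    bounds = model.param_bounds()
    tr = ParamTransform(bounds)
    w, ybar, within = _rss_parts(times, values)  # fit the mean trajectory; same optimum

    design = getattr(model, "design_matrix", None)
    if design is not None:
        # linear-in-parameters family: weighted least squares is exact
        X = np.asarray(design(times), dtype=float)
        sw = np.sqrt(w)
        params, *_ = np.linalg.lstsq(X * sw[:, None], ybar * sw, rcond=None)
        rss = _rss(model, params, times, values)
        n_obs = int(np.isfinite(values).sum())
        k = model.n_params
        sigma2 = max(rss / n_obs, 1e-300)
        aic = n_obs * np.log(sigma2) + 2 * k
        bic = n_obs * np.log(sigma2) + k * np.log(n_obs)
        return CurveFit(model, params, rss, float(aic), float(bic), n_obs)

    def obj(z):
        pred = model.value(tr.from_unconstrained(z), times)
        v = float(w @ ((ybar - pred) ** 2)) + within
        return v if np.isfinite(v) else 1e100

    z0 = tr.to_unconstrained(x0)
    best = optimize.minimize(obj, z0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        zj = z0 + 0.1 * rng.standard_normal(z0.shape) * (1.0 + np.abs(z0))
        res = optimize.minimize(obj, zj, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if res.fun < best.fun:
            best = res

    params = tr.from_unconstrained(best.x)
    rss = _rss(model, params, times, values)
    rss0 = _rss(model, x0, times, values)
    if rss > rss0 + 1e-9:  # descent guarantee relative to the initial guess
        params, rss = x0, rss0
    n_obs = int(np.isfinite(values).sum())
    k = model.n_params
    sigma2 = max(rss / n_obs, 1e-300)
    aic = n_obs * np.log(sigma2) + 2 * k
    bic = n_obs * np.log(sigma2) + k * np.log(n_obs)
    return CurveFit(model, params, rss, float(aic), float(bic), n_obs)


def select_curve(
    candidates: list[CurveModel] | list[str],
    times: np.ndarray,
    values: np.ndarray,
    criterion: str = "AIC",
) -> CurveFit:
    """Fit every candidate and return the one with the smallest criterion.

    Ties break toward fewer parameters, then toward earlier candidate order.
    """
    if criterion.upper() not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    if not candidates:
        raise ValueError("need at least one candidate curve")
    models = [get_curve(c) if isinstance(c, str) else c for c in candidates]
    fits: list[tuple[float, int, int, CurveFit]] = []
    errors = []
    for rank, m in enumerate(models):
        try:
            f = fit_curve_ls(m, times, values)
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(f"{m.name}: {exc}")
            continue
        crit = f.aic if criterion.upper() == "AIC" else f.bic
        fits.append((crit, m.n_params, rank, f))
    if not fits:
        raise FitError("all curve fits failed: " + "; ".join(errors))
    fits.sort(key=lambda t: (round(t[0], 9), t[1], t[2]))
    return fits[0][3]
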