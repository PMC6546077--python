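"""Bounded-parameter transforms and a small wrapper around scipy optimizers.

All model fitting in this package happens in an unconstrained space: each
bounded parameter is mapped through log / scaled-atanh so that generic
quasi-Newton and simplex optimizers never step outside its open interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

_ATANH_CLIP = 1.0 - 1e-12
_Z_CLIP = 40.0  # tanh/exp saturate well before this


@dataclass(frozen=True)
class IntervalTransform:
    """Bijection between an open interval (lo, hi) and the real line.

    (-inf, inf) -> identity; (0, inf) -> log; finite (lo, hi) -> scaled atanh.
    (-inf, hi) is handled by reflection of the (lo, inf) case.
    """

    lo: float
    hi: float

    def to_unconstrained(self, x: float) -> float:
        lo, hi = self.lo, self.hi
        if np.isinf(lo) and np.isinf(hi):
            return float(x)
        if np.isinf(hi):
            return float(np.log(max(x - lo, 1e-300)))
        if np.isinf(lo):
            return float(-np.log(max(hi - x, 1e-300)))
        u = (2.0 * (x - lo) / (hi - lo)) - 1.0
        return float(np.arctanh(np.clip(u, -_ATANH_CLIP, _ATANH_CLIP)))

    def from_unconstrained(self, z: float) -> float:
        lo, hi = self.lo, self.hi
        z = float(np.clip(z, -_Z_CLIP, _Z_CLIP))
        if np.isinf(lo) and np.isinf(hi):
            return z
        if np.isinf(hi):
            return lo + np.exp(z)
        if np.isinf(lo):
            return hi - np.exp(-z)
        return lo + (hi - lo) * 0.5 * (np.tanh(z) + 1.0)


class ParamTransform:
    """Vectorized :class:`IntervalTransform` for a list of bounds."""

    def __init__(self, bounds: Sequence[tuple[float, float]]):
        lo = np.array([b[0] for b in bounds], dtype=float)
        hi = np.array([b[1] for b in bounds], dtype=float)
        self.lo, self.hi = lo, hi
        self._free = np.isinf(lo) & np.isinf(hi)
        self._lower = ~np.isinf(lo) & np.isinf(hi)  # (lo, inf)
        self._upper = np.isinf(lo) & ~np.isinf(hi)  # (-inf, hi)
        self._both = ~np.isinf(lo) & ~np.isinf(hi)
        self._all_both = bool(self._both.all())
        self._span = np.where(self._both, hi - lo, 1.0)

    def __len__(self) -> int:
        return len(self.lo)

    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._all_both:
            u = 2.0 * (x - self.lo) / self._span - 1.0
            return np.arctanh(np.clip(u, -_ATANH_CLIP, _ATANH_CLIP))
        z = np.where(self._free, x, 0.0)
        with np.errstate(all="ignore"):
            if self._lower.any():
                z = np.where(self._lower, np.log(np.maximum(x - self.lo, 1e-300)), z)
            if self._upper.any():
                z = np.where(self._upper, -np.log(np.maximum(self.hi - x, 1e-300)), z)
            if self._both.any():
                u = 2.0 * (x - self.lo) / np.where(self._both, self.hi - self.lo, 1.0) - 1.0
                z = np.where(self._both, np.arctanh(np.clip(u, -_ATANH_CLIP, _ATANH_CLIP)), z)
        return z

    def from_unconstrained(self, z: np.ndarray) -> np.ndarray:
        z = np.clip(np.asarray(z, dtype=float), -_Z_CLIP, _Z_CLIP)
        if self._all_both:
            return self.lo + self._span * 0.5 * (np.tanh(z) + 1.0)
        x = np.where(self._free, z, 0.0)
        with np.errstate(all="ignore"):  # masked branches may overflow
            if self._lower.any():
                x = np.where(self._lower, self.lo + np.exp(z), x)
            if self._upper.any():
                x = np.where(self._upper, self.hi - np.exp(-z), x)
            if self._both.any():
                x = np.where(self._both, self.lo + (self.hi - self.lo) * 0.5 * (np.tanh(z) + 1.0), x)
        return x


def minimize_bounded(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    method: str = "L-BFGS-B",
    maxiter: int | None = None,
    restarts: int = 0,
    jitter: float = 0.05,
    seed: int = 0,
) -> optimize.OptimizeResult:
    """Minimize ``fun`` over its (open-interval) bounded domain.

    Works in transformed space; non-finite objective values are replaced by a
    large penalty so simplex/quasi-Newton methods survive singular corners.
    Optional restarts jitter the transformed starting point deterministically.
    """
    tr = ParamTransform(bounds)
    z0 = tr.to_unconstrained(np.asarray(x0, dtype=float))

    def zfun(z: np.ndarray) -> float:
        v = fun(tr.from_unconstrained(z))
        if not np.isfinite(v):
            return 1e100
        return float(v)

    opts = {} if maxiter is None else {"maxiter": maxiter}
    best = optimize.minimize(zfun, z0, method=method, options=opts)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            zj = z0 + jitter * rng.standard_normal(z0.shape) * (1.0 + np.abs(z0))
            res = optimize.minimize(zfun, zj, method=method, options=opts)
            if res.fun < best.fun:
                best = res
    best.x = tr.from_unconstrained(best.x)
    return best
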