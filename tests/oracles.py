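"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: densities use
explicit inverses and determinants, mixtures use double loops, and genotype
probabilities come from Monte-Carlo meiosis simulation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_mvn_logpdf(y, mean, sigma):
    """Textbook MVN log-density via explicit inverse and determinant."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    k = len(y)
    d = y - mean
    inv = np.linalg.inv(sigma)
    det = np.linalg.det(sigma)
    return float(-0.5 * (k * math.log(2 * math.pi) + math.log(det) + d @ inv @ d))


def naive_genotype_density(y_i, X_i, alpha, g_j, sigma):
    """Direct transcription of the genotype-conditional density."""
    mean = np.asarray(g_j, dtype=float).copy()
    if X_i is not None and alpha is not None and np.size(alpha):
        mean = mean + float(np.dot(np.atleast_1d(X_i), np.atleast_1d(alpha)))
    return naive_mvn_logpdf(y_i, mean, sigma)


def naive_mixture_loglik(Y, probs, G, sigma):
    """Double-loop mixture log-likelihood: sum_i log sum_j p_ij f_j(y_i)."""
    total = 0.0
    for i in range(Y.shape[0]):
        acc = 0.0
        for j in range(probs.shape[1]):
            acc += probs[i, j] * math.exp(naive_mvn_logpdf(Y[i], G[j], sigma))
        total += math.log(acc)
    return total


def haldane_r_oracle(d_cm):
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def mc_conditional_probs(cross_name, d_left, d_right, n_meioses, rng):
    """Monte-Carlo estimate of P(QTL genotype | left, right marker genotype).

    Simulates three-locus gametes (left marker, QTL, right marker) with
    independent crossovers in the two intervals.  Returns a dict keyed by the
    (left, right) genotype pair -> (J-vector of probabilities, counts).
    For RIL the per-interval recombination fractions are expanded to
    r* = 2r/(1+2r) (selfed-RIL observable recombination).
    """
    r1 = haldane_r_oracle(d_left)
    r2 = haldane_r_oracle(d_right)
    if cross_name == "RIL":
        r1 = 2 * r1 / (1 + 2 * r1)
        r2 = 2 * r2 / (1 + 2 * r2)

    def gametes():
        l = (rng.random(n_meioses) < 0.5).astype(int)
        q = np.where(rng.random(n_meioses) < r1, 1 - l, l)
        r = np.where(rng.random(n_meioses) < r2, 1 - q, q)
        return l, q, r

    if cross_name == "F2":
        l1, q1, rr1 = gametes()
        l2, q2, rr2 = gametes()
        l, q, r = l1 + l2, q1 + q2, rr1 + rr2
        J = 3
    else:  # BC, DH, RIL: one observable chain
        l, q, r = gametes()
        J = 2

    out = {}
    for lg in range(J):
        for rg in range(J):
            sel = (l == lg) & (r == rg)
            cnt = int(sel.sum())
            if cnt == 0:
                continue
            p = np.bincount(q[sel], minlength=J) / cnt
            out[(lg, rg)] = (p, cnt)
    return out


def ar1_loglik_tridiagonal(y, mean, s2, rho):
    """Closed-form AR(1) Gaussian log-likelihood via the known tridiagonal
    inverse/determinant: det = s2^m (1-rho^2)^(m-1)."""
    y = np.asarray(y, dtype=float) - np.asarray(mean, dtype=float)
    m = len(y)
    if m == 1:
        return float(-0.5 * (math.log(2 * math.pi * s2) + y[0] ** 2 / s2))
    logdet = m * math.log(s2) + (m - 1) * math.log(1 - rho**2)
    # quadratic form of the tridiagonal inverse
    q = y[0] ** 2 + y[-1] ** 2 + (1 + rho**2) * np.sum(y[1:-1] ** 2) - 2 * rho * np.sum(y[:-1] * y[1:])
    q /= s2 * (1 - rho**2)
    return float(-0.5 * (m * math.log(2 * math.pi) + logdet + q))


def sad1_covariance_by_simulation(v, phi, n, rng):
    """Empirical covariance of the ante-dependence recursion
    y_1 = e_1, y_t = phi_t y_{t-1} + e_t with var(e_t) = v_t."""
    m = len(v)
    Y = np.empty((n, m))
    Y[:, 0] = rng.normal(0, math.sqrt(v[0]), n)
    for t in range(1, m):
        Y[:, t] = phi[t - 1] * Y[:, t - 1] + rng.normal(0, math.sqrt(v[t]), n)
    return np.cov(Y.T)
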