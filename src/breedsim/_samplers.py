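"""Gibbs samplers for the Bayesian-alphabet whole-genome regressions.

Single-site samplers with conjugate updates, compiled with numba.  All three
methods share the residual-update bookkeeping; they differ only in the prior
on the marker effects:

* BL   — double-exponential via the normal/exponential scale mixture
         (Park & Casella), with a common rate lambda^2 ~ Gamma.
* EBL  — marker-specific double-exponential: the rate of marker j is
         lambda^2 * eta2_j with eta2_j ~ Gamma(psi, theta); the small-theta
         limit makes the per-marker shrinkage nearly free, which is what
         turns the fit into a sparse association scan.
* BayesC — spike-and-slab with a common slab variance and inclusion
         probability pi (Beta-updated unless fixed).

Seeding uses numba's own global RNG (np.random.seed inside the jitted
function), which makes every fit bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gibbs_bl", "gibbs_ebl", "gibbs_bayesc"]

_BIG = 1e10


@njit(cache=True)
def _rinvgauss(mu: float, lam: float) -> float:
    """Inverse-Gaussian draw (Michael–Schucany–Haas)."""
    if mu > _BIG:
        mu = _BIG
    v = np.random.normal()
    y2 = v * v
    x = mu + (mu * mu * y2) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y2 + mu * mu * y2 * y2
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _rscaled_inv_chi2(df: float, scale_sum: float) -> float:
    """Draw sigma2 ~ scale_sum / chi2_df."""
    chi2 = 2.0 * np.random.gamma(df / 2.0, 1.0)
    if chi2 <= 0.0:
        chi2 = 1e-12
    return scale_sum / chi2


@njit(cache=True)
def gibbs_bl(X, y, niter, burnin, seed, r_lambda, delta_lambda, nu_e, s_e):
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = np.dot(X[:, j], X[:, j])
    mu = y.mean()
    beta = np.zeros(m)
    tau2 = np.ones(m)
    lam2 = 1.0
    sigma2e = max(y.var(), 1e-8)
    e = y - mu
    mu_sum = 0.0
    beta_sum = np.zeros(m)
    s2e_sum = 0.0
    lam2_sum = 0.0
    kept = 0
    for it in range(niter):
        # intercept
        mu_new = np.random.normal(mu + e.mean(), np.sqrt(sigma2e / n))
        e -= mu_new - mu
        mu = mu_new
        # marker effects
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            b_old = beta[j]
            rhs = np.dot(X[:, j], e) + xtx[j] * b_old
            c = xtx[j] + 1.0 / tau2[j]
            b_new = np.random.normal(rhs / c, np.sqrt(sigma2e / c))
            diff = b_old - b_new
            if diff != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * diff
            beta[j] = b_new
        # local scales
        sum_tau2 = 0.0
        sum_b2_tau = 0.0
        for j in range(m):
            b2 = beta[j] * beta[j]
            if b2 < 1e-20:
                b2 = 1e-20
            inv_t = _rinvgauss(np.sqrt(lam2 * sigma2e / b2), lam2)
            tau2[j] = 1.0 / inv_t
            sum_tau2 += tau2[j]
            sum_b2_tau += b2 * inv_t
        # global rate
        lam2 = np.random.gamma(m + r_lambda, 1.0 / (sum_tau2 / 2.0 + delta_lambda))
        # residual variance (beta variance is tau2 * sigma2e)
        sse = np.dot(e, e)
        sigma2e = _rscaled_inv_chi2(n + m + nu_e, sse + sum_b2_tau + nu_e * s_e)
        if it >= burnin:
            kept += 1
            mu_sum += mu
            beta_sum += beta
            s2e_sum += sigma2e
            lam2_sum += lam2
    return mu_sum / kept, beta_sum / kept, s2e_sum / kept, lam2_sum / kept


@njit(cache=True)
def gibbs_ebl(X, y, niter, burnin, seed, phi, omega, psi, theta, nu_e, s_e):
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = np.dot(X[:, j], X[:, j])
    mu = y.mean()
    beta = np.zeros(m)
    tau2 = np.ones(m)
    eta2 = np.ones(m)
    lam2 = 1.0
    sigma2e = max(y.var(), 1e-8)
    e = y - mu
    mu_sum = 0.0
    beta_sum = np.zeros(m)
    s2e_sum = 0.0
    kept = 0
    for it in range(niter):
        mu_new = np.random.normal(mu + e.mean(), np.sqrt(sigma2e / n))
        e -= mu_new - mu
        mu = mu_new
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            b_old = beta[j]
            rhs = np.dot(X[:, j], e) + xtx[j] * b_old
            c = xtx[j] + 1.0 / tau2[j]
            b_new = np.random.normal(rhs / c, np.sqrt(sigma2e / c))
            diff = b_old - b_new
            if diff != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * diff
            beta[j] = b_new
        sum_eta_tau2 = 0.0
        sum_b2_tau = 0.0
        for j in range(m):
            rate_j = lam2 * eta2[j]
            b2 = beta[j] * beta[j]
            if b2 < 1e-20:
                b2 = 1e-20
            inv_t = _rinvgauss(np.sqrt(rate_j * sigma2e / b2), rate_j)
            tau2[j] = 1.0 / inv_t
            sum_b2_tau += b2 * inv_t
            # marker-specific rate multiplier
            eta2[j] = np.random.gamma(psi + 1.0, 1.0 / (theta + lam2 * tau2[j] / 2.0))
            sum_eta_tau2 += eta2[j] * tau2[j]
        lam2 = np.random.gamma(m + phi, 1.0 / (sum_eta_tau2 / 2.0 + omega))
        sse = np.dot(e, e)
        sigma2e = _rscaled_inv_chi2(n + m + nu_e, sse + sum_b2_tau + nu_e * s_e)
        if it >= burnin:
            kept += 1
            mu_sum += mu
            beta_sum += beta
            s2e_sum += sigma2e
    return mu_sum / kept, beta_sum / kept, s2e_sum / kept


@njit(cache=True)
def gibbs_bayesc(
    X, y, niter, burnin, seed, pi0, estimate_pi, nu_e, s_e, nu_b, s_b
):
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = np.dot(X[:, j], X[:, j])
    mu = y.mean()
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    pi = pi0
    sigma2e = max(y.var(), 1e-8)
    sigma2b = max(s_b, 1e-8)
    e = y - mu
    mu_sum = 0.0
    beta_sum = np.zeros(m)
    pip_sum = np.zeros(m)
    s2e_sum = 0.0
    pi_sum = 0.0
    kept = 0
    for it in range(niter):
        mu_new = np.random.normal(mu + e.mean(), np.sqrt(sigma2e / n))
        e -= mu_new - mu
        mu = mu_new
        m_in = 0
        sum_b2 = 0.0
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            b_old = beta[j]
            r = np.dot(X[:, j], e) + xtx[j] * b_old
            v0 = xtx[j] * sigma2e
            v1 = v0 + xtx[j] * xtx[j] * sigma2b
            log_odds = (
                np.log(pi) - np.log(1.0 - pi)
                + 0.5 * (np.log(v0) - np.log(v1))
                + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
            )
            if log_odds > 35.0:
                p_in = 1.0
            elif log_odds < -35.0:
                p_in = 0.0
            else:
                p_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_in:
                c = xtx[j] + sigma2e / sigma2b
                b_new = np.random.normal(r / c, np.sqrt(sigma2e / c))
                delta[j] = 1
                m_in += 1
                sum_b2 += b_new * b_new
            else:
                b_new = 0.0
                delta[j] = 0
            diff = b_old - b_new
            if diff != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * diff
            beta[j] = b_new
        sigma2b = _rscaled_inv_chi2(m_in + nu_b, sum_b2 + nu_b * s_b)
        if estimate_pi:
            a = 1.0 + m_in
            b = 1.0 + m - m_in
            ga = np.random.gamma(a, 1.0)
            gb = np.random.gamma(b, 1.0)
            pi = ga / (ga + gb)
            pi = min(max(pi, 1e-4), 1.0 - 1e-4)
        sse = np.dot(e, e)
        sigma2e = _rscaled_inv_chi2(n + nu_e, sse + nu_e * s_e)
        if it >= burnin:
            kept += 1
            mu_sum += mu
            beta_sum += beta
            for j in range(m):
                pip_sum[j] += delta[j]
            s2e_sum += sigma2e
            pi_sum += pi
    return (
        mu_sum / kept,
        beta_sum / kept,
        pip_sum / kept,
        s2e_sum / kept,
        pi_sum / kept,
    )
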