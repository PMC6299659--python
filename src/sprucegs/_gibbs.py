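"""Numba Gibbs-sampler kernels for whole-genome regressions.

All samplers operate on a residual-update scheme: the current residual
r = y − μ − Z a is maintained and each marker effect is refreshed from its
normal full conditional.  Variances are drawn from scaled-inverse-χ² full
conditionals (σ² = (SS + df·S) / χ²_{n+df}).  Kernels are deterministic
given the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_inv_gaussian(mu: float, lam: float) -> float:
    """Michael–Schucany–Haas inverse-Gaussian draw."""
    nu = np.random.normal()
    y = nu * nu
    x = mu + (mu * mu * y) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    if x <= 0.0:
        return mu * mu / 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def brr_gibbs(
    Z: np.ndarray,
    y: np.ndarray,
    df_a: float,
    S_a: float,
    df_e: float,
    S_e: float,
    n_iter: int,
    burn_in: int,
    thin: int,
    seed: int,
    fix_sigma_m: float,
    fix_sigma_e: float,
):
    """Bayesian ridge regression: common marker variance σ²_m.

    ``fix_sigma_m``/``fix_sigma_e`` > 0 freeze that variance (degenerate
    prior), used by the closed-form ridge oracle checks.
    Returns (mu_chain, sm2_chain, se2_chain, effect_chain, effect_sum).
    """
    np.random.seed(seed)
    n, m = Z.shape
    zsq = np.empty(m)
    active = np.empty(m, dtype=np.bool_)
    for j in range(m):
        s = 0.0
        t = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
            t += Z[i, j]
        zsq[j] = s
        # a zero-variance column is collinear with the intercept: fix at 0
        active[j] = (s / n - (t / n) ** 2) > 1e-10
    a = np.zeros(m)
    mu = y.mean()
    r = y - mu
    sm2 = S_a if fix_sigma_m <= 0.0 else fix_sigma_m
    se2 = S_e if fix_sigma_e <= 0.0 else fix_sigma_e
    n_keep = (n_iter - burn_in) // thin
    mu_chain = np.empty(n_keep)
    sm2_chain = np.empty(n_keep)
    se2_chain = np.empty(n_keep)
    eff_chain = np.empty((n_keep, m))
    kept = 0
    for it in range(n_iter):
        # marker effects
        for j in range(m):
            if not active[j]:
                a[j] = 0.0
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * r[i]
            rhs += zsq[j] * a[j]
            cj = zsq[j] + se2 / sm2
            mean_j = rhs / cj
            new = mean_j + np.sqrt(se2 / cj) * np.random.normal()
            diff = new - a[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= Z[i, j] * diff
            a[j] = new
        # intercept (flat prior)
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        mu_new = mu + rbar + np.sqrt(se2 / n) * np.random.normal()
        shift = mu_new - mu
        for i in range(n):
            r[i] -= shift
        mu = mu_new
        # variances
        if fix_sigma_m <= 0.0:
            ssa = 0.0
            for j in range(m):
                ssa += a[j] * a[j]
            sm2 = (ssa + df_a * S_a) / np.random.chisquare(m + df_a)
        if fix_sigma_e <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            se2 = (sse + df_e * S_e) / np.random.chisquare(n + df_e)
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            mu_chain[kept] = mu
            sm2_chain[kept] = sm2
            se2_chain[kept] = se2
            for j in range(m):
                eff_chain[kept, j] = a[j]
            kept += 1
    return mu_chain, sm2_chain, se2_chain, eff_chain


@njit(cache=True)
def blasso_gibbs(
    Z: np.ndarray,
    y: np.ndarray,
    r_shape: float,
    delta_rate: float,
    df_e: float,
    S_e: float,
    n_iter: int,
    burn_in: int,
    thin: int,
    seed: int,
    fix_lambda2: float,
):
    """Bayesian LASSO (Park–Casella): a_j ~ N(0, τ²_j σ²_e), τ²_j ~ Exp(λ²/2·…).

    λ² ~ Gamma(r_shape, rate=delta_rate) hyperprior updated from its Gamma
    full conditional; ``fix_lambda2`` > 0 freezes λ².  Returns
    (mu_chain, lam2_chain, se2_chain, effect_chain, tau2_chain, ok_flag).
    """
    np.random.seed(seed)
    n, m = Z.shape
    zsq = np.empty(m)
    active = np.empty(m, dtype=np.bool_)
    for j in range(m):
        s = 0.0
        t = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
            t += Z[i, j]
        zsq[j] = s
        active[j] = (s / n - (t / n) ** 2) > 1e-10
    a = np.zeros(m)
    tau2 = np.ones(m)
    mu = y.mean()
    r = y - mu
    se2 = S_e
    lam2 = 1.0 if fix_lambda2 <= 0.0 else fix_lambda2
    n_keep = (n_iter - burn_in) // thin
    mu_chain = np.empty(n_keep)
    lam2_chain = np.empty(n_keep)
    se2_chain = np.empty(n_keep)
    eff_chain = np.empty((n_keep, m))
    tau2_sum = np.zeros(m)
    kept = 0
    ok = 1
    for it in range(n_iter):
        for j in range(m):
            if not active[j]:
                a[j] = 0.0
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * r[i]
            rhs += zsq[j] * a[j]
            cj = zsq[j] + 1.0 / tau2[j]
            mean_j = rhs / cj
            new = mean_j + np.sqrt(se2 / cj) * np.random.normal()
            diff = new - a[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= Z[i, j] * diff
            a[j] = new
        # intercept
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        mu_new = mu + rbar + np.sqrt(se2 / n) * np.random.normal()
        shift = mu_new - mu
        for i in range(n):
            r[i] -= shift
        mu = mu_new
        # τ²_j via inverse-Gaussian on 1/τ²_j (clamped for numeric safety)
        for j in range(m):
            if not active[j]:
                continue
            aj2 = a[j] * a[j]
            if aj2 < 1e-30:
                aj2 = 1e-30
            ig_mu = np.sqrt(lam2 * se2 / aj2)
            inv_tau2 = _sample_inv_gaussian(ig_mu, lam2)
            t2 = 1.0 / inv_tau2
            if t2 > 1e8:
                t2 = 1e8
            elif t2 < 1e-10:
                t2 = 1e-10
            tau2[j] = t2
        # λ²
        if fix_lambda2 <= 0.0:
            sum_tau2 = 0.0
            for j in range(m):
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(m + r_shape, 1.0 / (sum_tau2 / 2.0 + delta_rate))
            if lam2 > 1e12:
                ok = 0
                break
        # σ²_e (appears in likelihood and the effect prior)
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        ssa = 0.0
        for j in range(m):
            ssa += a[j] * a[j] / tau2[j]
        se2 = (sse + ssa + df_e * S_e) / np.random.chisquare(n + m + df_e)
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            mu_chain[kept] = mu
            lam2_chain[kept] = lam2
            se2_chain[kept] = se2
            for j in range(m):
                eff_chain[kept, j] = a[j]
                tau2_sum[j] += tau2[j]
            kept += 1
    return mu_chain, lam2_chain, se2_chain, eff_chain, tau2_sum, ok
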