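"""Single-site Gibbs samplers for the Bayesian-alphabet marker models.

One compiled kernel serves BayesA, BayesB and BayesC-pi; the variants differ
only in how the prior variance of a marker effect is structured:

* BayesA   — every marker in the model, its own variance with a scaled
             inverse-chi-square prior;
* BayesB   — spike-and-slab with per-marker slab variances and a fixed prior
             inclusion probability pi;
* BayesC-pi — spike-and-slab with one common slab variance and pi itself
             sampled from its Beta full conditional (uniform prior).

The kernel works on the training design matrix in Fortran order so each
marker column is contiguous, keeps a running residual, and accumulates
posterior means after burn-in.  All randomness comes from numba's internal
RNG seeded at entry, so a fixed seed reproduces the chain exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

VARIANT_A = 0
VARIANT_B = 1
VARIANT_CPI = 2


@njit(cache=True)
def gibbs_chain(
    Z,            # n x p training genotypes, Fortran order
    y,            # length-n phenotypes
    X,            # n x c fixed-effect covariates (c may be 0), Fortran order
    n_iter,
    burn_in,
    variant,      # VARIANT_A | VARIANT_B | VARIANT_CPI
    pi0,          # prior/initial inclusion probability
    update_pi,    # True only for BayesC-pi
    nu_b,
    s_b,          # scale of the marker-variance prior
    nu_e,
    s_e,          # scale of the residual-variance prior
    seed,
):
    np.random.seed(seed)
    n, p = Z.shape
    c = X.shape[1]

    zsq = np.empty(p)
    for k in range(p):
        acc = 0.0
        for t in range(n):
            acc += Z[t, k] * Z[t, k]
        zsq[k] = acc
    xsq = np.empty(c)
    for j in range(c):
        acc = 0.0
        for t in range(n):
            acc += X[t, j] * X[t, j]
        xsq[j] = acc

    beta = np.zeros(p)
    alpha = np.zeros(c)
    in_model = np.ones(p, dtype=np.uint8)
    sigma_b = np.full(p, nu_b * s_b / (nu_b - 2.0))  # per-marker slab variances
    sigma_b_common = nu_b * s_b / (nu_b - 2.0)
    mu = y.mean()
    yvar = y.var()
    sigma_e = 0.5 * yvar if yvar > 0.0 else 1.0
    pi = pi0

    r = y - mu  # running residual y - mu - Z beta (beta starts at 0)

    beta_mean = np.zeros(p)
    alpha_mean = np.zeros(c)
    mu_mean = 0.0
    pi_mean = 0.0
    sigma_e_mean = 0.0
    n_samples = 0

    for it in range(n_iter):
        # intercept
        mu_new = np.random.normal(mu + r.mean(), np.sqrt(sigma_e / n))
        shift = mu_new - mu
        for t in range(n):
            r[t] -= shift
        mu = mu_new

        # fixed-effect covariates, flat prior
        for j in range(c):
            if xsq[j] == 0.0:
                continue
            a_old = alpha[j]
            rhs = 0.0
            for t in range(n):
                rhs += X[t, j] * r[t]
            rhs += xsq[j] * a_old
            a_new = np.random.normal(rhs / xsq[j], np.sqrt(sigma_e / xsq[j]))
            diff = a_old - a_new
            for t in range(n):
                r[t] += X[t, j] * diff
            alpha[j] = a_new

        n_in = 0
        ssq_in = 0.0
        for k in range(p):
            if zsq[k] == 0.0:  # monomorphic in the training set
                beta[k] = 0.0
                in_model[k] = 0
                continue
            b_old = beta[k]
            rhs = 0.0
            for t in range(n):
                rhs += Z[t, k] * r[t]
            rhs += zsq[k] * b_old

            if variant == 2:
                s2 = sigma_b_common
            else:
                s2 = sigma_b[k]
            C = zsq[k] + sigma_e / s2

            keep = True
            if variant != 0:
                # spike-and-slab: inclusion from the marginal likelihood ratio
                log_bf = 0.5 * (
                    rhs * rhs / (sigma_e * C)
                    + np.log(sigma_e) - np.log(s2) - np.log(C)
                )
                log_odds = np.log(pi / (1.0 - pi)) + log_bf
                if log_odds > 35.0:
                    p1 = 1.0
                elif log_odds < -35.0:
                    p1 = 0.0
                else:
                    odds = np.exp(log_odds)
                    p1 = odds / (1.0 + odds)
                keep = np.random.random() <= p1

            if keep:
                b_new = np.random.normal(rhs / C, np.sqrt(sigma_e / C))
                in_model[k] = 1
                n_in += 1
                ssq_in += b_new * b_new
            else:
                b_new = 0.0
                in_model[k] = 0

            diff = b_old - b_new
            if diff != 0.0:
                for t in range(n):
                    r[t] += Z[t, k] * diff
            beta[k] = b_new

        # marker-variance updates
        if variant == 0:
            for k in range(p):
                sigma_b[k] = (nu_b * s_b + beta[k] * beta[k]) / np.random.chisquare(
                    nu_b + 1.0
                )
        elif variant == 1:
            for k in range(p):
                if in_model[k] == 1:
                    sigma_b[k] = (
                        nu_b * s_b + beta[k] * beta[k]
                    ) / np.random.chisquare(nu_b + 1.0)
                else:
                    sigma_b[k] = nu_b * s_b / np.random.chisquare(nu_b)
        else:
            sigma_b_common = (nu_b * s_b + ssq_in) / np.random.chisquare(
                nu_b + n_in
            )
            if update_pi:
                pi = np.random.beta(1.0 + n_in, 1.0 + (p - n_in))
                if pi < 1e-6:
                    pi = 1e-6
                elif pi > 1.0 - 1e-6:
                    pi = 1.0 - 1e-6

        # residual variance
        sse = 0.0
        for t in range(n):
            sse += r[t] * r[t]
        sigma_e = (sse + nu_e * s_e) / np.random.chisquare(n + nu_e)
        if not np.isfinite(sigma_e) or sigma_e <= 0.0:
            raise ValueError("residual variance diverged during Gibbs sampling")

        if it >= burn_in:
            for k in range(p):
                beta_mean[k] += beta[k]
            for j in range(c):
                alpha_mean[j] += alpha[j]
            mu_mean += mu
            pi_mean += pi
            sigma_e_mean += sigma_e
            n_samples += 1

    inv = 1.0 / n_samples
    for k in range(p):
        beta_mean[k] *= inv
    for j in range(c):
        alpha_mean[j] *= inv
    return beta_mean, alpha_mean, mu_mean * inv, pi_mean * inv, sigma_e_mean * inv
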