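"""Numba Gibbs-sampler kernel shared by the Bayesian whole-genome regressions.

One compiled routine serves the five priors of the Bayesian alphabet; the
``model`` code selects the marker-effect prior:

====  =======  =======================================================
code  name     marker-effect prior
====  =======  =======================================================
0     BRR      u_j ~ N(0, s2_u), one common variance
1     BayesA   u_j ~ N(0, s2_j), s2_j ~ scaled-inv-chi2(nu, S)
2     BayesB   point mass at 0 w.p. pi, else as BayesA
3     BayesC   point mass at 0 w.p. pi, else N(0, s2_u); pi ~ Beta
4     BL       u_j ~ N(0, tau2_j s2_e), 1/tau2_j inverse-Gaussian
               (Bayesian LASSO, double-exponential marginal)
====  =======  =======================================================

All full conditionals are conjugate (single-site updates on the running
residual); the residual variance follows a scaled-inverse-chi-square.
Seeding goes through numba's internal RNG so chains are bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

BRR, BAYES_A, BAYES_B, BAYES_C, BL = 0, 1, 2, 3, 4


@njit(cache=False)
def _rinvgauss(mu: float, lam: float) -> float:
    """Inverse-Gaussian draw (Michael–Schucany–Haas)."""
    v = np.random.standard_normal()
    y = v * v
    x = (mu + mu * mu * y / (2.0 * lam)
         - mu / (2.0 * lam) * math.sqrt(4.0 * mu * lam * y + mu * mu * y * y))
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=False)
def gibbs_wgr(y, Z, model, n_iter, burn_in, thin, seed,
              nu, S_u, nu_e, S_e, pi0, estimate_pi,
              update_variances, su2_init, se2_init,
              bl_shape, bl_rate, lambda2_init):
    """Run the Gibbs chain; returns posterior means and a status flag.

    Returns
    -------
    (u_mean, mu_mean, se2_mean, su2_mean, pi_mean, incl_mean, status)
    status 0 = ok, 1 = divergent residual variance (non-finite).
    """
    np.random.seed(seed)
    n, p = Z.shape
    zz = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s

    u = np.zeros(p)
    sigma_j2 = np.full(p, su2_init)
    tau2 = np.ones(p)
    incl = np.ones(p, dtype=np.uint8)
    mu = y.mean()
    e = y - mu
    su2 = su2_init
    se2 = se2_init
    pi = pi0
    lambda2 = lambda2_init

    u_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    se2_sum = 0.0
    su2_sum = 0.0
    pi_sum = 0.0
    n_kept = 0

    for it in range(n_iter):
        # intercept
        mu_new = (mu + e.mean()) + np.random.standard_normal() * math.sqrt(se2 / n)
        for i in range(n):
            e[i] += mu - mu_new
        mu = mu_new

        sum_u2_incl = 0.0
        n_incl = 0
        sum_u2_over_tau2 = 0.0

        for j in range(p):
            if zz[j] <= 0.0:
                u[j] = 0.0
                continue
            r = 0.0
            for i in range(n):
                r += Z[i, j] * e[i]
            r += zz[j] * u[j]

            if model == BRR:
                varj = su2
            elif model == BAYES_A or model == BAYES_B:
                varj = sigma_j2[j]
            elif model == BAYES_C:
                varj = su2
            else:  # BL
                varj = tau2[j] * se2

            lam = se2 / varj
            c = zz[j] + lam
            u_old = u[j]

            if model == BAYES_B or model == BAYES_C:
                log_bf = 0.5 * (math.log(lam) - math.log(c)) \
                    + r * r / (2.0 * se2 * c)
                # numerically safe inclusion probability
                log_odds = math.log((1.0 - pi) / max(pi, 1e-300)) + log_bf
                if log_odds > 35.0:
                    p_in = 1.0
                elif log_odds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + math.exp(-log_odds))
                if np.random.random() < p_in:
                    incl[j] = 1
                    u_new = r / c + np.random.standard_normal() * math.sqrt(se2 / c)
                else:
                    incl[j] = 0
                    u_new = 0.0
            else:
                u_new = r / c + np.random.standard_normal() * math.sqrt(se2 / c)

            if u_new != u_old:
                d = u_new - u_old
                for i in range(n):
                    e[i] -= Z[i, j] * d
            u[j] = u_new

            if model == BAYES_A:
                sigma_j2[j] = (S_u * nu + u[j] * u[j]) \
                    / np.random.chisquare(nu + 1.0)
            elif model == BAYES_B:
                if incl[j] == 1:
                    sigma_j2[j] = (S_u * nu + u[j] * u[j]) \
                        / np.random.chisquare(nu + 1.0)
                else:
                    sigma_j2[j] = S_u * nu / np.random.chisquare(nu)
            elif model == BAYES_C:
                if incl[j] == 1:
                    sum_u2_incl += u[j] * u[j]
                    n_incl += 1
            elif model == BL:
                uj2 = max(u[j] * u[j], 1e-12)
                itau = _rinvgauss(math.sqrt(lambda2 * se2 / uj2), lambda2)
                tau2[j] = 1.0 / itau
                sum_u2_over_tau2 += uj2 / tau2[j]

        # variance components
        if model == BRR and update_variances:
            s = 0.0
            for j in range(p):
                s += u[j] * u[j]
            su2 = (S_u * nu + s) / np.random.chisquare(nu + p)
        elif model == BAYES_C:
            su2 = (S_u * nu + sum_u2_incl) / np.random.chisquare(nu + n_incl)
            if estimate_pi:
                a = 1.0 + (p - n_incl)
                b = 1.0 + n_incl
                pi = np.random.beta(a, b)
        elif model == BL:
            s_tau = 0.0
            for j in range(p):
                s_tau += tau2[j]
            lambda2 = np.random.gamma(bl_shape + p,
                                      1.0 / (bl_rate + 0.5 * s_tau))

        if update_variances:
            ete = 0.0
            for i in range(n):
                ete += e[i] * e[i]
            if model == BL:
                se2 = (ete + sum_u2_over_tau2 + S_e * nu_e) \
                    / np.random.chisquare(n + p + nu_e)
            else:
                se2 = (ete + S_e * nu_e) / np.random.chisquare(n + nu_e)
        if not math.isfinite(se2) or se2 <= 0.0:
            return u_sum, mu_sum, se2_sum, su2_sum, pi_sum, incl_sum, 1

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            for j in range(p):
                u_sum[j] += u[j]
                incl_sum[j] += incl[j]
            mu_sum += mu
            se2_sum += se2
            if model == BAYES_A or model == BAYES_B:
                sm = 0.0
                for j in range(p):
                    sm += sigma_j2[j]
                su2_sum += sm / p
            elif model == BL:
                su2_sum += lambda2
            else:
                su2_sum += su2
            pi_sum += pi

    if n_kept == 0:
        return u_sum, mu_sum, se2_sum, su2_sum, pi_sum, incl_sum, 1
    k = float(n_kept)
    return (u_sum / k, mu_sum / k, se2_sum / k, su2_sum / k,
            pi_sum / k, incl_sum / k, 0)
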