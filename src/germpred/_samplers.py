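"""Numba-jitted marker-sweep kernels for the Gibbs samplers.

Only the sequential part of each sampler lives here: the single-site
updates of marker effects (and inclusion indicators for the mixture
model), which must visit markers one at a time against a shared residual
vector.  All random numbers are drawn outside from a seeded numpy
Generator and passed in, so runs are bit-reproducible and independent of
numba's internal RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def sweep_bayes_b(X, e, b, delta, var_b, c, sigma2_e, log_prior_odds, z, u):
    """One Gibbs sweep over markers for the point-mass/normal mixture model.

    Parameters
    ----------
    X : (n, p) column-contiguous design (centered dosages)
    e : residual vector, updated in place
    b, delta : current effects and inclusion indicators, updated in place
    var_b : per-marker slab variances sigma2_bl
    c : per-marker sum of squares x_l'x_l
    log_prior_odds : log((1 - pi) / pi), pi = null proportion
    z, u : length-p standard normals and uniforms

    Returns the number of included markers.
    """
    n, p = X.shape
    n_in = 0
    for l in range(p):
        bl = b[l]
        if bl != 0.0:
            for i in range(n):
                e[i] += X[i, l] * bl
        r = 0.0
        for i in range(n):
            r += X[i, l] * e[i]
        cl = c[l]
        v = var_b[l]
        denom = cl * v + sigma2_e
        log_bf = 0.5 * (np.log(sigma2_e) - np.log(denom)) + 0.5 * r * r * v / (
            sigma2_e * denom
        )
        # P(delta_l = 1 | rest) through the logistic of log odds
        lo = log_prior_odds + log_bf
        if lo > 35.0:
            p_in = 1.0
        elif lo < -35.0:
            p_in = 0.0
        else:
            p_in = 1.0 / (1.0 + np.exp(-lo))
        if u[l] < p_in:
            prec = cl + sigma2_e / v
            mean = r / prec
            sd = np.sqrt(sigma2_e / prec)
            b_new = mean + sd * z[l]
            b[l] = b_new
            delta[l] = 1
            n_in += 1
            for i in range(n):
                e[i] -= X[i, l] * b_new
        else:
            b[l] = 0.0
            delta[l] = 0
    return n_in


@njit(cache=False, fastmath=False)
def sweep_lasso(X, e, b, inv_tau2, c, sigma2_e, z):
    """One Gibbs sweep of marker effects for the double-exponential prior.

    Conditional on tau2, each effect is Gaussian:
    ``b_l | . ~ N(r / (c_l + 1/tau2_l), sigma2_e / (c_l + 1/tau2_l))``.
    """
    n, p = X.shape
    for l in range(p):
        bl = b[l]
        if bl != 0.0:
            for i in range(n):
                e[i] += X[i, l] * bl
        r = 0.0
        for i in range(n):
            r += X[i, l] * e[i]
        prec = c[l] + inv_tau2[l]
        mean = r / prec
        sd = np.sqrt(sigma2_e / prec)
        b_new = mean + sd * z[l]
        b[l] = b_new
        for i in range(n):
            e[i] -= X[i, l] * b_new
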