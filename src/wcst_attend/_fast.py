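"""Compiled fast path for the per-block log-likelihood.

The model-inversion objective evaluates a full belief filter plus response
likelihood for every optimizer query; this module provides numba-jitted
implementations of that inner loop, numerically equivalent (to ~1e-10) to the
reference implementations in :mod:`wcst_attend.perceptual` and
:mod:`wcst_attend.response`, which remain the module surface.  If numba is
unavailable the package transparently falls back to the reference path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


_LOG_2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _response_ll(m, P, x_clr, sum_log_r):
    """Logistic-normal log density at a precomputed clr-transformed response."""
    # explicit 3x3 inverse / determinant
    a = P[0, 0]; b = P[0, 1]; c = P[0, 2]
    d = P[1, 1]; e = P[1, 2]; f = P[2, 2]
    det = a * (d * f - e * e) - b * (b * f - c * e) + c * (b * e - c * d)
    if det <= 0.0 or not np.isfinite(det):
        return -np.inf
    i00 = (d * f - e * e) / det
    i01 = (c * e - b * f) / det
    i02 = (b * e - c * d) / det
    i11 = (a * f - c * c) / det
    i12 = (b * c - a * e) / det
    i22 = (a * d - b * b) / det
    d0 = x_clr[0] - m[0]
    d1 = x_clr[1] - m[1]
    d2 = x_clr[2] - m[2]
    quad = (
        i00 * d0 * d0 + i11 * d1 * d1 + i22 * d2 * d2
        + 2.0 * (i01 * d0 * d1 + i02 * d0 * d2 + i12 * d1 * d2)
    )
    apa = a + d + f + 2.0 * (b + c + e)
    am = m[0] + m[1] + m[2]
    log_n = -0.5 * (3.0 * _LOG_2PI + np.log(det) + quad)
    log_z = -0.5 * np.log(2.0 * np.pi * apa) - am * am / (2.0 * apa)
    return log_n - log_z - np.log(3.0) - sum_log_r


@njit(cache=True)
def bayes_block_loglik(
    e_seq,          # (T, 6) float64 binary
    clr_r,          # (T, 3) clr of clamped observed responses
    sum_log_r,      # (T,)   sum of log response components after clamping
    reduced,        # bool
    W_lat_e,        # (6, 6)
    W_lat_f,        # (3, 3)
    W_dist_fe,      # (6, 3)
    W_dist_ef,      # (3, 6)
    kappa_e, kappa_f, tau_e, tau_f, q_e, q_f,
    error_rate,
    mu0,            # (dim,)
    sigma_e0, sigma_f0,
    theta1, theta2, theta3,
):
    """Summed response log-likelihood of one block under a Bayesian variant."""
    T = e_seq.shape[0]
    dim = 6 if reduced else 9
    mu = mu0.copy()
    Sigma = np.zeros((dim, dim))
    for i in range(6):
        Sigma[i, i] = sigma_e0
    if not reduced:
        for i in range(6, 9):
            Sigma[i, i] = sigma_f0
    total = 0.0
    eye = np.eye(dim)
    for t in range(T):
        # --- propagate mean and Jacobian
        g = np.empty(dim)
        J = np.zeros((dim, dim))
        phi_e = _sigmoid(mu[:6] - kappa_e)
        dphi_e = phi_e * (1.0 - phi_e)
        for i in range(6):
            acc = tau_e * mu[i] + kappa_e
            for j in range(6):
                acc += W_lat_e[i, j] * phi_e[j]
                J[i, j] = W_lat_e[i, j] * dphi_e[j]
            J[i, i] += tau_e
            g[i] = acc
        if not reduced:
            phi_f = _sigmoid(mu[6:] - kappa_f)
            dphi_f = phi_f * (1.0 - phi_f)
            for i in range(6):
                for j in range(3):
                    g[i] += W_dist_fe[i, j] * phi_f[j]
                    J[i, 6 + j] = W_dist_fe[i, j] * dphi_f[j]
            for i in range(3):
                acc = tau_f * mu[6 + i] + kappa_f
                for j in range(3):
                    acc += W_lat_f[i, j] * phi_f[j]
                    J[6 + i, 6 + j] = W_lat_f[i, j] * dphi_f[j]
                for j in range(6):
                    acc += W_dist_ef[i, j] * phi_e[j]
                    J[6 + i, j] = W_dist_ef[i, j] * dphi_e[j]
                J[6 + i, 6 + i] += tau_f
                g[6 + i] = acc
        # --- predicted covariance
        Sig_hat = J @ Sigma @ J.T
        for i in range(6):
            Sig_hat[i, i] += q_e
        if not reduced:
            for i in range(6, 9):
                Sig_hat[i, i] += q_f
        # --- hypothesis posterior
        gmax = g[0]
        for i in range(1, 6):
            if g[i] > gmax:
                gmax = g[i]
        z = np.exp(g[:6] - gmax)
        zsum = z.sum()
        pi = z / zsum
        rho = np.empty(6)
        for i in range(6):
            lik = 1.0 - error_rate if e_seq[t, i] == 1.0 else error_rate
            rho[i] = lik * z[i]
        rho /= rho.sum()
        # --- Gaussian update: Sigma = Sigma_hat (I + Y Sigma_hat)^-1
        Y = np.zeros((dim, dim))
        for i in range(6):
            for j in range(6):
                Y[i, j] = -pi[i] * pi[j]
            Y[i, i] += pi[i]
        # (Sig_hat^-1 + Y)^-1 = (I + Sig_hat Y)^-1 Sig_hat
        Sigma = np.linalg.solve(eye + Sig_hat @ Y, Sig_hat)
        Sigma = 0.5 * (Sigma + Sigma.T)
        delta = np.zeros(dim)
        for i in range(6):
            delta[i] = rho[i] - pi[i]
        mu = g + Sigma @ delta
        # --- response likelihood
        m_vec = np.empty(3)
        P = np.zeros((3, 3))
        if reduced:
            emax = mu[0]
            for i in range(1, 6):
                if mu[i] > emax:
                    emax = mu[i]
            w = np.exp(mu[:6] - emax)
            wsum = w.sum()
            for i in range(3):
                p_i = (w[2 * i] + w[2 * i + 1]) / wsum
                if p_i < 1e-300:
                    p_i = 1e-300
                m_vec[i] = np.log(p_i)
            mbar = (m_vec[0] + m_vec[1] + m_vec[2]) / 3.0
            for i in range(3):
                m_vec[i] = theta1 * (m_vec[i] - mbar)
            for i in range(3):
                P[i, i] = theta2
        else:
            for i in range(3):
                m_vec[i] = theta1 * mu[6 + i]
            for i in range(3):
                for j in range(3):
                    P[i, j] = theta3 * Sigma[6 + i, 6 + j]
                P[i, i] += theta2
        ll = _response_ll(m_vec, P, clr_r[t], sum_log_r[t])
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


@njit(cache=True)
def nonbayes_block_loglik(
    e_seq, clr_r, sum_log_r,
    reduced,
    W_lat_e, W_lat_f, W_dist_fe, W_dist_ef,
    kappa_e, kappa_f, tau_e, tau_f,
    evidence_weight, alpha,
    mu0,
    theta1, theta2,
):
    """Summed response log-likelihood under a non-Bayesian (fixed-gain) variant."""
    T = e_seq.shape[0]
    dim = 6 if reduced else 9
    mu = mu0.copy()
    total = 0.0
    for t in range(T):
        g = np.empty(dim)
        phi_e = _sigmoid(mu[:6] - kappa_e)
        for i in range(6):
            acc = tau_e * mu[i] + kappa_e
            for j in range(6):
                acc += W_lat_e[i, j] * phi_e[j]
            g[i] = acc
        if not reduced:
            phi_f = _sigmoid(mu[6:] - kappa_f)
            for i in range(6):
                for j in range(3):
                    g[i] += W_dist_fe[i, j] * phi_f[j]
            for i in range(3):
                acc = tau_f * mu[6 + i] + kappa_f
                for j in range(3):
                    acc += W_lat_f[i, j] * phi_f[j]
                for j in range(6):
                    acc += W_dist_ef[i, j] * phi_e[j]
                g[6 + i] = acc
        gmax = g[0]
        for i in range(1, 6):
            if g[i] > gmax:
                gmax = g[i]
        z = np.exp(g[:6] - gmax)
        pi = z / z.sum()
        mu = g.copy()
        for i in range(6):
            rho_i = 1.0 - evidence_weight if e_seq[t, i] == 1.0 else evidence_weight
            mu[i] = g[i] + alpha * (rho_i - pi[i])
        m_vec = np.empty(3)
        P = np.zeros((3, 3))
        if reduced:
            emax = mu[0]
            for i in range(1, 6):
                if mu[i] > emax:
                    emax = mu[i]
            w = np.exp(mu[:6] - emax)
            wsum = w.sum()
            for i in range(3):
                p_i = (w[2 * i] + w[2 * i + 1]) / wsum
                if p_i < 1e-300:
                    p_i = 1e-300
                m_vec[i] = np.log(p_i)
            mbar = (m_vec[0] + m_vec[1] + m_vec[2]) / 3.0
            for i in range(3):
                m_vec[i] = theta1 * (m_vec[i] - mbar)
        else:
            for i in range(3):
                m_vec[i] = theta1 * mu[6 + i]
        for i in range(3):
            P[i, i] = theta2
        ll = _response_ll(m_vec, P, clr_r[t], sum_log_r[t])
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total
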