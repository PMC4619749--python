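"""Response models: from beliefs to money allocations on the 2-simplex.

Subjects report beliefs by splitting $20 across the three visual features.  The
modeled response is a power-weighted composition of the feature-relevance
probabilities p_t -- the exponent theta1 is an inverse risk factor -- perturbed
by Gaussian noise on log-ratio coordinates.  The resulting likelihood of an
observed allocation is a multivariate logistic-normal density evaluated at the
centered log-ratio (clr) transform of the response, with a normalization
constant Z accounting for the projection of R^3 onto the zero-sum plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perceptual import BeliefState, PerceptualVariant, softmax

#: projection vector of the plane constraint sum(x) = const
A_VEC = np.ones(3)

TOTAL_MONEY = 20.0

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class ResponseParams:
    """theta1: inverse risk factor (>0); theta2: baseline response-noise
    variance (>0); theta3: weight of the belief-uncertainty noise component
    (0 in the reduced response model)."""

    theta1: float = 1.0
    theta2: float = 1.0
    theta3: float = 0.0


@dataclass
class ResponseDensity:
    """Location m, covariance P and normalization constant Z of the
    logistic-normal response density at one trial."""

    m: np.ndarray
    P: np.ndarray
    Z: float


def feature_probs(mu: np.ndarray, variant: PerceptualVariant) -> np.ndarray:
    """Posterior probability that each visual feature is currently relevant.

    Full-hierarchy variants: softmax of the feature-level means.  Reduced
    variants: each feature's probability sums its two exemplars' softmax mass.
    """
    mu = np.asarray(mu, dtype=float)
    if variant.reduced:
        z = np.exp(mu[:6] - mu[:6].max())
        p = z.reshape(3, 2).sum(axis=1)
        return p / p.sum()
    return softmax(mu[6:])


def optimal_response(p: np.ndarray, theta1: float) -> np.ndarray:
    """Risk-adjusted allocation r = p^theta1 / sum(p^theta1).

    theta1 -> 0 yields the uniform (maximally risk-averse) allocation; large
    theta1 concentrates the bet on the most probable feature.
    """
    if theta1 < 0:
        raise ValueError("theta1 must be nonnegative")
    p = np.asarray(p, dtype=float)
    # power on log scale for stability at large theta1
    logw = theta1 * np.log(p)
    return softmax(logw)


def clr(r: np.ndarray, *, floor: float | None = None) -> np.ndarray:
    """Centered log-ratio transform: ln(r / geometric mean(r)); sums to zero.

    ``floor`` projects boundary compositions to the interior (components
    clipped below at ``floor``, then renormalized) before taking logs.
    """
    r = np.asarray(r, dtype=float)
    if floor is not None:
        r = np.clip(r, floor, None)
        r = r / r.sum()
    if np.any(r <= 0):
        raise ValueError("clr requires strictly positive components")
    logr = np.log(r)
    return logr - logr.mean()


def clamp_simplex(r: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Project an observed composition to the interior of the simplex."""
    r = np.clip(np.asarray(r, dtype=float), floor, None)
    return r / r.sum()


def response_covariance(theta: ResponseParams, Sigma_f: np.ndarray | None = None) -> np.ndarray:
    """Response-noise covariance P = theta2 I + theta3 Sigma_f.

    Sigma_f (the feature-level belief covariance) is only available for
    Bayesian full-hierarchy perceptual models; elsewhere theta3 = 0 and
    P = theta2 I.
    """
    P = theta.theta2 * np.eye(3)
    if Sigma_f is not None:
        Sigma_f = np.asarray(Sigma_f, dtype=float)
        eigs = np.linalg.eigvalsh(0.5 * (Sigma_f + Sigma_f.T))
        if eigs.min() < -1e-10:
            raise ValueError("Sigma_f must be positive semidefinite")
        P = P + theta.theta3 * Sigma_f
    elif theta.theta3 != 0.0:
        raise ValueError("theta3 > 0 requires a dynamic feature covariance")
    return 0.5 * (P + P.T)


def response_density(
    belief: BeliefState,
    variant: PerceptualVariant | None,
    theta: ResponseParams,
    *,
    baseline_mu_f0: np.ndarray | None = None,
) -> ResponseDensity:
    """Location and covariance of the response distribution at one trial.

    m = theta1 mu_f for full-hierarchy perceptual models, theta1 clr(p) for
    reduced ones; the baseline model uses its fixed mean mu_f0 with
    P = (1 + theta3) I.
    """
    if baseline_mu_f0 is not None:
        m = np.asarray(baseline_mu_f0, dtype=float)
        P = (1.0 + theta.theta3) * np.eye(3)
    elif variant.reduced:
        p = np.clip(feature_probs(belief.mu, variant), 1e-300, None)
        m = theta.theta1 * clr(p)
        P = response_covariance(ResponseParams(theta.theta1, theta.theta2, 0.0))
    else:
        m = theta.theta1 * belief.mu[6:]
        Sigma_f = belief.Sigma[6:, 6:] if theta.theta3 != 0.0 else None
        P = response_covariance(theta, Sigma_f)
    return ResponseDensity(m=m, P=P, Z=lognormal_constant(m, P))


def sample_response(m: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one stochastic allocation: softmax(m + xi), xi ~ N(0, P).

    Equivalent to perturbing the optimal power-weighted response on the log
    scale and renormalizing onto the simplex.
    """
    xi = rng.multivariate_normal(np.zeros(3), P, method="cholesky")
    return softmax(np.asarray(m, dtype=float) + xi)


def lognormal_constant(m: np.ndarray, P: np.ndarray) -> float:
    """Normalization constant Z = (2 pi a'Pa)^(-1/2) exp(-(a'm)^2 / (2 a'Pa)),
    the marginal Gaussian density of the off-plane coordinate a'x at zero."""
    return float(np.exp(lognormal_logconstant(m, P)))


def lognormal_logconstant(m: np.ndarray, P: np.ndarray) -> float:
    """ln Z, computed directly so tiny covariances cannot underflow."""
    m = np.asarray(m, dtype=float)
    s = float(A_VEC @ P @ A_VEC)
    am = float(A_VEC @ m)
    return -0.5 * am * am / s - 0.5 * np.log(2.0 * np.pi * s)


def response_loglik(
    r: np.ndarray,
    belief: BeliefState | None,
    variant: PerceptualVariant | None,
    theta: ResponseParams,
    *,
    baseline_mu_f0: np.ndarray | None = None,
    floor: float = 1e-3,
) -> float:
    """Log logistic-normal likelihood of an observed allocation r.

    log p(r) = log N(clr(r); m, P) - log Z - log 3 - sum(log r_i).
    """
    dens = response_density(belief, variant, theta, baseline_mu_f0=baseline_mu_f0)
    r = clamp_simplex(r, floor)
    x = clr(r)
    diff = x - dens.m
    sign, logdet = np.linalg.slogdet(dens.P)
    if sign <= 0:
        raise ValueError("response covariance must be positive definite")
    quad = float(diff @ np.linalg.solve(dens.P, diff))
    log_norm = -0.5 * (3 * _LOG_2PI + logdet + quad)
    return (log_norm - lognormal_logconstant(dens.m, dens.P) - np.log(3.0)
            - float(np.log(r).sum()))


def response_to_money(r: np.ndarray, total: float = TOTAL_MONEY) -> np.ndarray:
    """Convert a simplex allocation to dollars; components sum to ``total``."""
    r = np.asarray(r, dtype=float)
    return total * r
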