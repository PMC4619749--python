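"""Perceptual models: belief dynamics over rule hypotheses in the card sorting task.

The hidden state ``h_t`` stacks the relevance of the six exemplar-feature pairs
(``h_e``, red/green color, left/right motion, circle/square shape) and, for the
full-hierarchy variants, the relevance of the three visual features (``h_f``).
Between trials the state evolves under winner-take-all (WTA) attractor dynamics:
leaky integration plus lateral inhibition within a level and symmetric
excitation between levels.  Observing which card the experimenter picked then
updates the belief either through an approximate (variational) Bayesian filter
-- a Gaussian belief with mean and covariance -- or through a fixed-gain,
Rescorla-Wagner-like prediction-error rule (the non-Bayesian variants).

Six structural variants are supported:

========  =====  ======================================================
variant   state  structure
========  =====  ======================================================
``w1``    9      lateral inhibition on both levels (kappa_e, kappa_f > 0)
``w2``    9      inhibition only on the feature level (kappa_e = 0)
``w3``    9      inhibition only on the exemplar level (kappa_f = 0)
``d``     9      no inhibition anywhere (diffusive, structure-free)
``rw``    6      exemplar level only, with inhibition
``rd``    6      exemplar level only, diffusive
========  =====  ======================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

N_EXEMPLARS = 6
N_FEATURES = 3
N_HYPOTHESES = 6

FULL_STRUCTURES = ("w1", "w2", "w3", "d")
REDUCED_STRUCTURES = ("rw", "rd")
STRUCTURES = FULL_STRUCTURES + REDUCED_STRUCTURES

#: feature index of each exemplar: (red, green) -> color, (left, right) -> motion,
#: (circle, square) -> shape
FEATURE_OF_EXEMPLAR = np.repeat(np.arange(N_FEATURES), 2)


def sigmoid(x):
    """Logistic activation phi(x) = 1 / (1 + exp(-x)), overflow-safe."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def sigmoid_deriv(x):
    """phi'(x) = phi(x) (1 - phi(x))."""
    s = sigmoid(x)
    return s * (1.0 - s)


def softmax(x):
    x = np.asarray(x, dtype=float)
    z = np.exp(x - x.max())
    return z / z.sum()


@dataclass(frozen=True)
class PerceptualVariant:
    """One of the six state-space structures, Bayesian or not."""

    structure: str
    bayesian: bool = True

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")

    @property
    def reduced(self) -> bool:
        return self.structure in REDUCED_STRUCTURES

    @property
    def dim(self) -> int:
        return N_EXEMPLARS if self.reduced else N_EXEMPLARS + N_FEATURES

    @property
    def kappa_e_free(self) -> bool:
        return self.structure in ("w1", "w3", "rw")

    @property
    def kappa_f_free(self) -> bool:
        return self.structure in ("w1", "w2")


@dataclass
class PerceptualParams:
    """Parameters of the belief dynamics.

    All fields default to the structurally-fixed value 0 (or a neutral value)
    so that a variant only reads the fields it owns.

    error_rate      subjective experimenter error rate (epsilon, Bayesian), in (0, 1/2)
    evidence_weight evidence weight of the non-Bayesian update, in (0, 1/2)
    tau_e, tau_f    leak / time-scale of each level, in (1/2, 1)
    kappa_e, kappa_f  inhibition threshold; lateral weight is w_lat = 2 kappa
    q_e, q_f        process-noise variances
    w_dist          symmetric between-level excitation
    mu_e0, mu_f0    shared scalar initial means per level
    sigma_e0, sigma_f0  initial belief variances
    alpha           fixed posterior variance of the non-Bayesian update
    """

    error_rate: float = 0.25
    tau_e: float = 0.75
    tau_f: float = 0.75
    kappa_e: float = 0.0
    kappa_f: float = 0.0
    q_e: float = 0.1
    q_f: float = 0.1
    w_dist: float = 0.0
    mu_e0: float = 0.0
    mu_f0: float = 0.0
    sigma_e0: float = 1.0
    sigma_f0: float = 1.0
    alpha: float = 1.0
    evidence_weight: float = 0.25

    def replace(self, **kw) -> "PerceptualParams":
        return replace(self, **kw)


@dataclass
class Connectivity:
    """Connectivity matrices of the two-level network.

    ``W_lat_*`` carry the lateral inhibition (-2 kappa off-diagonal, 0 on the
    diagonal); ``W_dist_fe`` feeds feature activity into the exemplar level
    (w_dist at (i, v(i))) and ``W_dist_ef`` is its transpose.
    """

    W_lat_e: np.ndarray
    W_lat_f: np.ndarray | None = None
    W_dist_fe: np.ndarray | None = None
    W_dist_ef: np.ndarray | None = None


def build_connectivity(
    variant: PerceptualVariant,
    params: PerceptualParams,
    *,
    bidirectional_d: bool = False,
) -> Connectivity:
    """Construct the connectivity for a variant.

    For the structure-free variant ``d`` the default wiring keeps only the
    bottom-up excitation (exemplar level -> feature level); set
    ``bidirectional_d=True`` for symmetric coupling on both paths.
    """
    if params.kappa_e < 0 or params.kappa_f < 0 or params.w_dist < 0:
        raise ValueError("kappa and w_dist must be nonnegative")
    kappa_e = params.kappa_e if variant.kappa_e_free else 0.0
    W_lat_e = -2.0 * kappa_e * (np.ones((6, 6)) - np.eye(6))
    if variant.reduced:
        return Connectivity(W_lat_e=W_lat_e)
    kappa_f = params.kappa_f if variant.kappa_f_free else 0.0
    W_lat_f = -2.0 * kappa_f * (np.ones((3, 3)) - np.eye(3))
    W_dist_fe = np.zeros((6, 3))
    W_dist_fe[np.arange(6), FEATURE_OF_EXEMPLAR] = params.w_dist
    W_dist_ef = W_dist_fe.T.copy()
    if variant.structure == "d" and not bidirectional_d:
        W_dist_fe = np.zeros((6, 3))
    return Connectivity(W_lat_e, W_lat_f, W_dist_fe, W_dist_ef)


def _effective_kappas(variant, params):
    ke = params.kappa_e if variant.kappa_e_free else 0.0
    kf = params.kappa_f if variant.kappa_f_free else 0.0
    return ke, kf


def propagate_mean(
    mu: np.ndarray,
    variant: PerceptualVariant,
    params: PerceptualParams,
    conn: Connectivity | None = None,
) -> np.ndarray:
    """Noise-free state propagation g(mu) over one trial.

    g_e = tau_e h_e + kappa_e + W_lat_e phi(h_e - kappa_e) + W_dist_fe phi(h_f - kappa_f)
    g_f = tau_f h_f + kappa_f + W_lat_f phi(h_f - kappa_f) + W_dist_ef phi(h_e - kappa_e)
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (variant.dim,):
        raise ValueError(f"state must have shape ({variant.dim},)")
    if conn is None:
        conn = build_connectivity(variant, params)
    ke, kf = _effective_kappas(variant, params)
    h_e = mu[:6]
    phi_e = sigmoid(h_e - ke)
    g_e = params.tau_e * h_e + ke + conn.W_lat_e @ phi_e
    if variant.reduced:
        return g_e
    h_f = mu[6:]
    phi_f = sigmoid(h_f - kf)
    g_e = g_e + conn.W_dist_fe @ phi_f
    g_f = params.tau_f * h_f + kf + conn.W_lat_f @ phi_f + conn.W_dist_ef @ phi_e
    return np.concatenate([g_e, g_f])


def jacobian_g(
    mu: np.ndarray,
    variant: PerceptualVariant,
    params: PerceptualParams,
    conn: Connectivity | None = None,
) -> np.ndarray:
    """Closed-form Jacobian of :func:`propagate_mean` at ``mu``."""
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (variant.dim,):
        raise ValueError(f"state must have shape ({variant.dim},)")
    if conn is None:
        conn = build_connectivity(variant, params)
    ke, kf = _effective_kappas(variant, params)
    d_e = sigmoid_deriv(mu[:6] - ke)
    J_ee = params.tau_e * np.eye(6) + conn.W_lat_e * d_e[np.newaxis, :]
    if variant.reduced:
        return J_ee
    d_f = sigmoid_deriv(mu[6:] - kf)
    J = np.zeros((9, 9))
    J[:6, :6] = J_ee
    J[:6, 6:] = conn.W_dist_fe * d_f[np.newaxis, :]
    J[6:, 6:] = params.tau_f * np.eye(3) + conn.W_lat_f * d_f[np.newaxis, :]
    J[6:, :6] = conn.W_dist_ef * d_e[np.newaxis, :]
    return J


@dataclass
class BeliefState:
    """Gaussian belief over the hidden state: mean and covariance."""

    mu: np.ndarray
    Sigma: np.ndarray


@dataclass
class PredictedBelief:
    """One-step-ahead belief: mean g(mu) and covariance J Sigma J' + Q."""

    mean: np.ndarray
    cov: np.ndarray


@dataclass
class HypothesisPosterior:
    """Categorical posterior over the six rule hypotheses plus the quantities
    entering the Gaussian belief update.

    rho      posterior hypothesis probabilities (normalized)
    pi_pred  predicted probabilities, softmax of the exemplar part of g(mu)
    delta    prediction error rho - pi_pred, zero-padded to the state dimension
    Y        curvature diag(pi) - pi pi' on the exemplar block, zero elsewhere
    """

    rho: np.ndarray
    pi_pred: np.ndarray
    delta: np.ndarray
    Y: np.ndarray


def process_noise(variant: PerceptualVariant, params: PerceptualParams) -> np.ndarray:
    if variant.reduced:
        return params.q_e * np.eye(6)
    return np.diag(np.concatenate([np.full(6, params.q_e), np.full(3, params.q_f)]))


def initial_belief(variant: PerceptualVariant, params: PerceptualParams) -> BeliefState:
    """Symmetric initial belief: shared scalar mean and isotropic variance per level."""
    if variant.reduced:
        mu0 = np.full(6, params.mu_e0)
        S0 = params.sigma_e0 * np.eye(6)
    else:
        mu0 = np.concatenate([np.full(6, params.mu_e0), np.full(3, params.mu_f0)])
        S0 = np.diag(
            np.concatenate([np.full(6, params.sigma_e0), np.full(3, params.sigma_f0)])
        )
    if not variant.bayesian:
        S0 = params.alpha * np.eye(variant.dim)
    return BeliefState(mu=mu0, Sigma=S0)


def predict_belief(
    belief: BeliefState,
    variant: PerceptualVariant,
    params: PerceptualParams,
    conn: Connectivity | None = None,
) -> PredictedBelief:
    """Propagate a Gaussian belief through the linearized dynamics."""
    if conn is None:
        conn = build_connectivity(variant, params)
    mean = propagate_mean(belief.mu, variant, params, conn)
    J = jacobian_g(belief.mu, variant, params, conn)
    cov = J @ belief.Sigma @ J.T + process_noise(variant, params)
    cov = 0.5 * (cov + cov.T)
    return PredictedBelief(mean=mean, cov=cov)


def hypothesis_posterior(
    e: np.ndarray, pred_mean: np.ndarray, error_rate: float
) -> HypothesisPosterior:
    """Posterior over the six hypotheses after seeing the experimenter's choice.

    rho_k is proportional to p(e_k | epsilon) exp(g_k) with
    p(e_k | epsilon) = 1 - epsilon if exemplar k is on the chosen card, else
    epsilon; the exponential weighting by the predicted relevance g_k is the
    attention-like gating of evidence.
    """
    e = np.asarray(e)
    if e.shape != (6,) or not np.all((e == 0) | (e == 1)) or e.sum() != 3:
        raise ValueError("e must be binary of length 6 with exactly three ones")
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 1/2)")
    pred_mean = np.asarray(pred_mean, dtype=float)
    g_e = pred_mean[:6]
    lik = np.where(e == 1, 1.0 - error_rate, error_rate)
    # softmax with evidence weights, max-shifted for overflow safety
    z = np.exp(g_e - g_e.max())
    pi_pred = z / z.sum()
    rho = lik * z
    rho = rho / rho.sum()
    dim = pred_mean.shape[0]
    delta = np.zeros(dim)
    delta[:6] = rho - pi_pred
    Y = np.zeros((dim, dim))
    Y[:6, :6] = np.diag(pi_pred) - np.outer(pi_pred, pi_pred)
    return HypothesisPosterior(rho=rho, pi_pred=pi_pred, delta=delta, Y=Y)


def bayes_update(pred: PredictedBelief, hyp: HypothesisPosterior) -> BeliefState:
    """Gaussian belief update from the quadratic expansion of the variational
    energy around the predicted mean: Sigma = (Sigma_hat^-1 + Y)^-1, one Newton
    step mu = g + Sigma delta."""
    dim = pred.mean.shape[0]
    try:
        Sigma = np.linalg.inv(np.linalg.inv(pred.cov) + hyp.Y)
    except np.linalg.LinAlgError:
        # degenerate parameters can drive Sigma_hat numerically singular
        jitter = 1e-8 * np.eye(dim)
        Sigma = np.linalg.inv(np.linalg.inv(pred.cov + jitter) + hyp.Y + jitter)
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = pred.mean + Sigma @ hyp.delta
    return BeliefState(mu=mu, Sigma=Sigma)


def nonbayes_update(
    mu: np.ndarray,
    e: np.ndarray,
    variant: PerceptualVariant,
    params: PerceptualParams,
    conn: Connectivity | None = None,
    *,
    normalize_rho: bool = False,
) -> np.ndarray:
    """Fixed-gain prediction-error update (Rescorla-Wagner-like).

    The evidence vector rho has entries 1 - evidence_weight where the chosen
    card carries the exemplar and evidence_weight otherwise; it is left
    unnormalized by default (``normalize_rho`` offers the normalized variant
    for sensitivity analysis).  Only the exemplar level receives the
    prediction-error correction, scaled by the fixed variance alpha.
    """
    ew = params.evidence_weight
    if not 0.0 < ew < 0.5:
        raise ValueError("evidence_weight must lie in (0, 1/2)")
    e = np.asarray(e)
    g = propagate_mean(mu, variant, params, conn)
    rho = np.where(e == 1, 1.0 - ew, ew)
    if normalize_rho:
        rho = rho / rho.sum()
    g_e = g[:6]
    z = np.exp(g_e - g_e.max())
    pi = z / z.sum()
    new = g.copy()
    new[:6] = g_e + params.alpha * (rho - pi)
    return new


@dataclass
class FilterResult:
    """Belief trajectory over a block.

    ``beliefs`` has T+1 entries (initial state included); ``posteriors`` has one
    :class:`HypothesisPosterior` per trial (Bayesian variants) or the
    unnormalized evidence vectors (non-Bayesian).
    """

    beliefs: list
    posteriors: list
    variant: PerceptualVariant = field(default=None)

    @property
    def means(self) -> np.ndarray:
        return np.array([b.mu for b in self.beliefs])

    def to_frame(self):
        """Trajectory as a DataFrame (one row per state, trial 0 = initial
        belief): mean components plus marginal variances, for downstream
        regressor use."""
        import pandas as pd

        labels = ["red", "green", "left", "right", "circle", "square",
                  "color", "motion", "shape"][: self.beliefs[0].mu.size]
        rows = []
        for t, b in enumerate(self.beliefs):
            row = {"trial": t}
            row.update({f"mu_{lab}": b.mu[i] for i, lab in enumerate(labels)})
            row.update({f"var_{lab}": b.Sigma[i, i]
                        for i, lab in enumerate(labels)})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-ready trajectory: means and flattened covariances per state."""
        return {
            "means": [b.mu.tolist() for b in self.beliefs],
            "covariances": [b.Sigma.flatten().tolist() for b in self.beliefs],
        }


def _e_matrix(block_or_e) -> np.ndarray:
    if hasattr(block_or_e, "e_matrix"):
        return block_or_e.e_matrix()
    e = np.asarray(block_or_e)
    if e.ndim != 2 or e.shape[1] != 6:
        raise ValueError("expected a Block or a (T, 6) binary choice matrix")
    return e


def run_filter(block_or_e, variant_or_model, params: PerceptualParams) -> FilterResult:
    """Run a perceptual model over a block's choice sequence.

    Accepts a :class:`~wcst_attend.task.Block` or a (T, 6) binary matrix, and a
    :class:`PerceptualVariant` (or anything with a ``.perceptual`` attribute,
    e.g. a ModelSpec).
    """
    variant = getattr(variant_or_model, "perceptual", variant_or_model)
    e_seq = _e_matrix(block_or_e)
    conn = build_connectivity(variant, params)
    state = initial_belief(variant, params)
    beliefs = [state]
    posteriors = []
    if variant.bayesian:
        for e in e_seq:
            pred = predict_belief(state, variant, params, conn)
            hyp = hypothesis_posterior(e, pred.mean, params.error_rate)
            state = bayes_update(pred, hyp)
            beliefs.append(state)
            posteriors.append(hyp)
    else:
        S = params.alpha * np.eye(variant.dim)
        for e in e_seq:
            mu = nonbayes_update(state.mu, e, variant, params, conn)
            state = BeliefState(mu=mu, Sigma=S)
            beliefs.append(state)
            posteriors.append(np.where(e == 1, 1.0 - params.evidence_weight,
                                       params.evidence_weight))
    return FilterResult(beliefs=beliefs, posteriors=posteriors, variant=variant)
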