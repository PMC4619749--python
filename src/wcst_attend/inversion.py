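"""Model inversion: fit one behavioral model to one (or several) blocks.

All free parameters are mapped to an unconstrained real vector ``chi`` so the
prior and the Laplace posterior are multivariate normal there.  The log-joint
(summed per-trial response log-likelihood plus Gaussian log-prior) is maximized
with a multi-restart derivative-free search; the Laplace approximation to the
log model evidence is

    ln p(r | e)  ~=  l(beta) + 1/2 ln |2 pi S|,     S = -H(beta)^-1,

with H the numerically estimated Hessian of the log-joint at the mode beta.
Following the study procedure, the Hessian and Laplace evidence are computed
for every restart's solution and the restart with the largest evidence is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _fast
from .models import ModelSpec
from .perceptual import PerceptualParams, build_connectivity, run_filter
from .response import ResponseParams, response_loglik

#: route objective evaluations through the numba fast path when available;
#: the reference implementation is always used for the baseline model
USE_FAST = _fast.HAVE_NUMBA

_LOG_2PI = math.log(2.0 * math.pi)

# transform kinds: natural domain -> R
#   log:  (0, inf),      chi = ln z
#   eps:  (0, 1/2),      chi = ln(2z / (1 - 2z))
#   tau:  (1/2, 1),      chi = ln((2z - 1) / (2 (1 - z)))
#   id:   R
_PERC_LAYOUT = [
    ("error_rate", "eps"),
    ("evidence_weight", "eps"),
    ("tau_e", "tau"),
    ("tau_f", "tau"),
    ("kappa_e", "log"),
    ("kappa_f", "log"),
    ("q_e", "log"),
    ("q_f", "log"),
    ("w_dist", "log"),
    ("mu_e0", "id"),
    ("mu_f0", "id"),
    ("sigma_e0", "log"),
    ("sigma_f0", "log"),
    ("alpha", "log"),
]
_RESP_LAYOUT = [("theta1", "log"), ("theta2", "log"), ("theta3", "log")]


def param_layout(model: ModelSpec) -> list[tuple[str, str]]:
    """Ordered (name, transform) pairs of a model's free parameters."""
    if model.baseline:
        return [
            ("mu_f0_color", "id"),
            ("mu_f0_motion", "id"),
            ("mu_f0_shape", "id"),
            ("theta3", "log"),
        ]
    v = model.perceptual
    names = {"tau_e", "mu_e0", "theta1", "theta2"}
    names.add("error_rate" if v.bayesian else "evidence_weight")
    if v.kappa_e_free:
        names.add("kappa_e")
    if v.bayesian:
        names.update({"q_e", "sigma_e0"})
    else:
        names.add("alpha")
    if not v.reduced:
        names.update({"tau_f", "w_dist", "mu_f0"})
        if v.kappa_f_free:
            names.add("kappa_f")
        if v.bayesian:
            names.update({"q_f", "sigma_f0"})
    if model.response == "full":
        names.add("theta3")
    return [(n, k) for n, k in _PERC_LAYOUT + _RESP_LAYOUT if n in names]


def n_params(model: ModelSpec) -> int:
    return len(param_layout(model))


def _fwd(z: float, kind: str) -> float:
    if kind == "log":
        if z <= 0:
            raise ValueError("log-transformed parameter must be positive")
        return math.log(z)
    if kind == "eps":
        if not 0.0 < z < 0.5:
            raise ValueError("parameter must lie in (0, 1/2)")
        return math.log(2.0 * z / (1.0 - 2.0 * z))
    if kind == "tau":
        if not 0.5 < z < 1.0:
            raise ValueError("parameter must lie in (1/2, 1)")
        return math.log((2.0 * z - 1.0) / (2.0 * (1.0 - z)))
    return float(z)


def _inv(x: float, kind: str) -> float:
    if kind == "log":
        return math.exp(x)
    if kind == "eps":
        # z = sigmoid(x) / 2
        return 0.5 / (1.0 + math.exp(-x))
    if kind == "tau":
        # z = (1 + 2 e^x) / (2 (1 + e^x))
        s = 1.0 / (1.0 + math.exp(-x))
        return 0.5 * (1.0 + s)
    return float(x)


def to_unconstrained(values: dict[str, float], model: ModelSpec) -> np.ndarray:
    """Map natural-scale parameter values to the real vector chi."""
    return np.array([_fwd(values[n], k) for n, k in param_layout(model)])


def from_unconstrained(chi: np.ndarray, model: ModelSpec) -> dict[str, float]:
    layout = param_layout(model)
    chi = np.asarray(chi, dtype=float)
    if chi.shape != (len(layout),):
        raise ValueError(f"chi must have length {len(layout)}")
    return {n: _inv(x, k) for (n, k), x in zip(layout, chi)}


def materialize(values: dict[str, float], model: ModelSpec):
    """Build (PerceptualParams | None, ResponseParams, baseline mu_f0 | None)
    from a natural-scale parameter dict."""
    if model.baseline:
        mu_f0 = np.array([values["mu_f0_color"], values["mu_f0_motion"],
                          values["mu_f0_shape"]])
        return None, ResponseParams(1.0, 1.0, values["theta3"]), mu_f0
    perc_kw = {k: v for k, v in values.items()
               if k in PerceptualParams.__dataclass_fields__}
    resp_kw = {k: v for k, v in values.items()
               if k in ResponseParams.__dataclass_fields__}
    return PerceptualParams(**perc_kw), ResponseParams(**resp_kw), None


@dataclass
class PriorSpec:
    """Isotropic Gaussian prior N(chi; eta0, s_o I) in transformed space.

    eta0 = 0 corresponds to error rate 1/4, tau 3/4, positive parameters 1 and
    initial means 0 on the natural scale.
    """

    eta0: np.ndarray | None = None
    s_o: float = 2.0

    def mean(self, dim: int) -> np.ndarray:
        if self.eta0 is None:
            return np.zeros(dim)
        eta0 = np.asarray(self.eta0, dtype=float)
        if eta0.shape != (dim,):
            raise ValueError(f"eta0 must have length {dim}")
        return eta0

    def logpdf(self, chi: np.ndarray) -> float:
        d = chi.shape[0]
        diff = chi - self.mean(d)
        return float(
            -0.5 * (diff @ diff) / self.s_o - 0.5 * d * (_LOG_2PI + math.log(self.s_o))
        )


@dataclass
class OptimizerConfig:
    """Multi-restart derivative-free search settings.

    ``method`` selects the per-restart search: ``"cma"`` (covariance-matrix
    adaptation evolution strategy, the default) or ``"nelder-mead"``.  The
    study procedure used N = 50 restarts per block; ``fast()`` (5 restarts) is
    a cheaper preset for simulation studies.  ``population_size`` of ``None``
    uses the standard 4 + floor(3 ln d).
    """

    n_restarts: int = 50
    initial_step: float = 0.5
    max_evals: int = 20000
    method: str = "cma"
    population_size: int | None = None
    xatol: float = 1e-4
    fatol: float = 1e-6
    seed: int | None = None

    @classmethod
    def fast(cls, **kw) -> "OptimizerConfig":
        kw.setdefault("n_restarts", 5)
        kw.setdefault("max_evals", 8000)
        return cls(**kw)


def cma_es(
    objective,
    x0: np.ndarray,
    sigma0: float,
    rng: np.random.Generator,
    max_evals: int = 20000,
    population_size: int | None = None,
    ftol: float = 1e-8,
    sigma_stop: float = 1e-8,
):
    """Minimal (mu/mu_w, lambda) covariance-matrix-adaptation evolution
    strategy, maximizing ``objective``.

    Standard rank-mu + rank-one update with cumulative step-size adaptation;
    non-finite objective values rank last, so the search simply retreats from
    undefined regions.  Returns (best x, best f, n_evals).
    """
    n = x0.size
    lam = population_size or 4 + int(3 * math.log(n))
    mu = lam // 2
    w = math.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / float(w @ w)
    c_sigma = (mu_eff + 2.0) / (n + mu_eff + 5.0)
    d_sigma = 1.0 + 2.0 * max(0.0, math.sqrt((mu_eff - 1.0) / (n + 1.0)) - 1.0) + c_sigma
    c_c = (4.0 + mu_eff / n) / (n + 4.0 + 2.0 * mu_eff / n)
    c_1 = 2.0 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1.0 - c_1, 2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((n + 2.0) ** 2 + mu_eff))
    chi_n = math.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n * n))

    mean = x0.astype(float).copy()
    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)
    best_x, best_f = mean.copy(), objective(mean)
    n_evals = 1
    gen = 0
    while n_evals + lam <= max_evals:
        gen += 1
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)
        z = rng.standard_normal((lam, n))
        y = z * D @ B.T            # rows: B D z
        xs = mean + sigma * y
        fs = np.array([objective(x) for x in xs])
        n_evals += lam
        fs_rank = np.where(np.isfinite(fs), fs, -np.inf)
        order = np.argsort(-fs_rank)
        if fs_rank[order[0]] > best_f:
            best_f = float(fs_rank[order[0]])
            best_x = xs[order[0]].copy()
        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w
        # step-size path in the isotropic coordinates
        c_inv_half = B @ ((B / D).T)   # C^{-1/2}
        p_sigma = (1.0 - c_sigma) * p_sigma + math.sqrt(
            c_sigma * (2.0 - c_sigma) * mu_eff
        ) * (c_inv_half @ y_w)
        norm_ps = float(np.linalg.norm(p_sigma))
        h_sigma = norm_ps / math.sqrt(
            1.0 - (1.0 - c_sigma) ** (2.0 * gen)
        ) < (1.4 + 2.0 / (n + 1.0)) * chi_n
        p_c = (1.0 - c_c) * p_c + (
            math.sqrt(c_c * (2.0 - c_c) * mu_eff) * y_w if h_sigma else 0.0
        )
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1.0 - c_1 - c_mu) * C
            + c_1 * (np.outer(p_c, p_c) + (0.0 if h_sigma else c_c * (2.0 - c_c)) * C)
            + c_mu * rank_mu
        )
        C = 0.5 * (C + C.T)
        sigma *= math.exp((c_sigma / d_sigma) * (norm_ps / chi_n - 1.0))
        if sigma < sigma_stop:
            break
        finite = fs_rank[np.isfinite(fs_rank)]
        if finite.size == lam and float(finite.max() - finite.min()) < ftol:
            break
    return best_x, float(best_f), n_evals


@dataclass
class FitResult:
    model: ModelSpec
    chi_mode: np.ndarray
    params: dict[str, float]
    S: np.ndarray
    log_joint_at_mode: float
    log_evidence: float
    regularized: bool = False
    restart_log_joints: list = field(default_factory=list)
    restart_evidences: list = field(default_factory=list)


def _as_blocks(blocks) -> list:
    return blocks if isinstance(blocks, (list, tuple)) else [blocks]


def _block_arrays(block, floor: float = 1e-3):
    """Precompute the choice matrix and clamped clr-transformed responses."""
    e = np.asarray(block.e_matrix(), dtype=float)
    r = np.array([t.response for t in block.trials], dtype=float)
    r = np.clip(r, floor, None)
    r = r / r.sum(axis=1, keepdims=True)
    logr = np.log(r)
    clr_r = logr - logr.mean(axis=1, keepdims=True)
    return e, clr_r, logr.sum(axis=1)


def _fast_arrays_loglik(arrays, model: ModelSpec, perc: PerceptualParams,
                        resp: ResponseParams) -> float:
    """Fast-path likelihood over precomputed (e, clr_r, sum_log_r) triples."""
    v = model.perceptual
    conn = build_connectivity(v, perc)
    ke = perc.kappa_e if v.kappa_e_free else 0.0
    kf = perc.kappa_f if v.kappa_f_free else 0.0
    if v.reduced:
        mu0 = np.full(6, perc.mu_e0)
        W_lat_f = np.zeros((3, 3))
        W_dist_fe = np.zeros((6, 3))
        W_dist_ef = np.zeros((3, 6))
    else:
        mu0 = np.concatenate([np.full(6, perc.mu_e0), np.full(3, perc.mu_f0)])
        W_lat_f, W_dist_fe, W_dist_ef = conn.W_lat_f, conn.W_dist_fe, conn.W_dist_ef
    total = 0.0
    if v.bayesian:
        theta3 = resp.theta3 if model.response == "full" else 0.0
        for e, clr_r, sum_log_r in arrays:
            total += float(_fast.bayes_block_loglik(
                e, clr_r, sum_log_r, v.reduced,
                conn.W_lat_e, W_lat_f, W_dist_fe, W_dist_ef,
                ke, kf, perc.tau_e, perc.tau_f, perc.q_e, perc.q_f,
                perc.error_rate, mu0, perc.sigma_e0, perc.sigma_f0,
                resp.theta1, resp.theta2, theta3,
            ))
            if total == -np.inf:
                return -np.inf
    else:
        for e, clr_r, sum_log_r in arrays:
            total += float(_fast.nonbayes_block_loglik(
                e, clr_r, sum_log_r, v.reduced,
                conn.W_lat_e, W_lat_f, W_dist_fe, W_dist_ef,
                ke, kf, perc.tau_e, perc.tau_f,
                perc.evidence_weight, perc.alpha, mu0,
                resp.theta1, resp.theta2,
            ))
            if total == -np.inf:
                return -np.inf
    return total


def make_objective(blocks, model: ModelSpec, prior: PriorSpec | None = None):
    """Closure evaluating the log-joint with per-block arrays precomputed;
    equivalent to :func:`log_joint` but cheaper inside optimization loops."""
    if prior is None:
        prior = PriorSpec()
    blocks = _as_blocks(blocks)
    if model.baseline or not USE_FAST:
        return lambda chi: log_joint(chi, blocks, model, prior)
    arrays = [_block_arrays(b) for b in blocks if b.trials]

    def objective(chi):
        chi = np.asarray(chi, dtype=float)
        try:
            values = from_unconstrained(chi, model)
            perc, resp, _ = materialize(values, model)
            total = _fast_arrays_loglik(arrays, model, perc, resp)
            result = total + prior.logpdf(chi)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError,
                OverflowError):
            return -np.inf
        return result if np.isfinite(result) else -np.inf

    return objective


def log_joint(chi, blocks, model: ModelSpec, prior: PriorSpec | None = None) -> float:
    """Log-joint l(chi): summed response log-likelihood over all trials of all
    blocks plus the Gaussian log-prior.  Returns -inf where the likelihood is
    numerically undefined (sentinel for the optimizer)."""
    if prior is None:
        prior = PriorSpec()
    chi = np.asarray(chi, dtype=float)
    try:
        values = from_unconstrained(chi, model)
        perc, resp, mu_f0 = materialize(values, model)
        total = 0.0
        with np.errstate(over="raise", invalid="raise"):
            for block in _as_blocks(blocks):
                if model.baseline:
                    for t in block.trials:
                        total += response_loglik(t.response, None, None, resp,
                                                 baseline_mu_f0=mu_f0)
                elif USE_FAST:
                    if block.trials:
                        total += _fast_arrays_loglik([_block_arrays(block)],
                                                     model, perc, resp)
                else:
                    filt = run_filter(block, model, perc)
                    for t, belief in zip(block.trials, filt.beliefs[1:]):
                        total += response_loglik(t.response, belief,
                                                 model.perceptual, resp)
        result = total + prior.logpdf(chi)
    except (FloatingPointError, np.linalg.LinAlgError, ValueError, OverflowError):
        return -np.inf
    return result if np.isfinite(result) else -np.inf


def find_mode(
    objective,
    config: OptimizerConfig,
    dim: int,
    rng: np.random.Generator | None = None,
    start_sampler=None,
):
    """Maximize ``objective`` with ``config.n_restarts`` Nelder-Mead runs from
    dispersed starts; returns (best x, diagnostics dict).  Deterministic given
    the generator / seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if start_sampler is None:
        start_sampler = lambda r: r.normal(0.0, 1.0, size=dim)
    best_x, best_f = None, -np.inf
    xs, fs = [], []
    for _ in range(config.n_restarts):
        x0 = np.asarray(start_sampler(rng), dtype=float)
        if not np.isfinite(objective(x0)):
            x0 = np.zeros(dim)
        if config.method == "cma":
            x, f, _ = cma_es(
                objective,
                x0,
                config.initial_step,
                rng,
                max_evals=config.max_evals,
                population_size=config.population_size,
            )
            # cheap local polish of the evolution-strategy solution
            simplex = np.vstack([x, x + 0.05 * np.eye(dim)])
            res = optimize.minimize(
                lambda p: -objective(p), x, method="Nelder-Mead",
                options={"maxfev": max(200, dim * 100), "xatol": config.xatol,
                         "fatol": config.fatol, "initial_simplex": simplex},
            )
            if -res.fun > f:
                x, f = res.x, -res.fun
        elif config.method == "nelder-mead":
            simplex = np.vstack([x0, x0 + config.initial_step * np.eye(dim)])
            res = optimize.minimize(
                lambda p: -objective(p),
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": config.max_evals,
                    "xatol": config.xatol,
                    "fatol": config.fatol,
                    "initial_simplex": simplex,
                },
            )
            x, f = res.x, -res.fun
        else:
            raise ValueError(f"unknown optimizer method {config.method!r}")
        xs.append(x)
        fs.append(f)
        if f > best_f:
            best_x, best_f = x, f
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("all optimizer restarts returned non-finite objectives")
    return best_x, {"restart_x": xs, "restart_f": fs, "best_f": best_f}


def numerical_hessian(objective, x, step: float = 1e-3, richardson: bool = False):
    """Symmetric Hessian of ``objective`` at ``x`` by central differences.

    Per-coordinate steps scale with |x_i|; ``richardson=True`` adds one
    Richardson extrapolation level (halved step), roughly squaring the
    truncation order at double the cost.
    """
    x = np.asarray(x, dtype=float)

    def _central(h):
        d = x.size
        H = np.empty((d, d))
        f0 = objective(x)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h[i]
            H[i, i] = (objective(x + ei) - 2.0 * f0 + objective(x - ei)) / h[i] ** 2
            for j in range(i + 1, d):
                ej = np.zeros(d)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    objective(x + ei + ej)
                    - objective(x + ei - ej)
                    - objective(x - ei + ej)
                    + objective(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
        return H

    h = step * np.maximum(1.0, np.abs(x))
    H = _central(h)
    if richardson:
        H = (4.0 * _central(0.5 * h) - H) / 3.0
    H = 0.5 * (H + H.T)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite entries in numerical Hessian")
    return H


def laplace_log_evidence(log_joint_at_mode: float, hessian: np.ndarray):
    """Laplace approximation l(beta) + 1/2 ln|2 pi S| with S = -H^-1.

    A non-PD negative Hessian (numerically inevitable near boundary modes) is
    shifted by the smallest diagonal amount achieving positive definiteness;
    the returned flag records whether that was needed.
    """
    H = 0.5 * (hessian + hessian.T)
    neg = -H
    eigs, vecs = np.linalg.eigh(neg)
    regularized = bool(eigs.min() <= 0)
    if regularized:
        shift = -eigs.min() + 1e-6
        eigs = eigs + shift
    d = H.shape[0]
    # ln|2 pi S| = d ln 2pi - ln|-H|
    logdet_neg = float(np.sum(np.log(eigs)))
    evidence = log_joint_at_mode + 0.5 * (d * _LOG_2PI - logdet_neg)
    S = (vecs / eigs) @ vecs.T
    return evidence, S, regularized


def fit_block(
    blocks,
    model: ModelSpec,
    prior: PriorSpec | None = None,
    config: OptimizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit ``model`` to one block (or a list fitted jointly with shared
    parameters).  Every restart's solution gets its own Hessian and Laplace
    evidence; the restart with the largest evidence wins."""
    if prior is None:
        prior = PriorSpec()
    if config is None:
        config = OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dim = n_params(model)
    eta0 = prior.mean(dim)
    sd = math.sqrt(prior.s_o)

    objective = make_objective(blocks, model, prior)

    def sampler(r):
        return eta0 + sd * r.normal(size=dim)

    _, diag = find_mode(objective, config, dim, rng=rng, start_sampler=sampler)
    best = None
    evidences = []
    for x, f in zip(diag["restart_x"], diag["restart_f"]):
        if not np.isfinite(f):
            evidences.append(-np.inf)
            continue
        H = numerical_hessian(objective, x)
        ev, S, reg = laplace_log_evidence(f, H)
        evidences.append(ev)
        if best is None or ev > best[0]:
            best = (ev, x, f, S, reg)
    if best is None:
        raise RuntimeError("no restart produced a finite evidence")
    ev, x, f, S, reg = best
    return FitResult(
        model=model,
        chi_mode=x,
        params=from_unconstrained(x, model),
        S=S,
        log_joint_at_mode=f,
        log_evidence=ev,
        regularized=reg,
        restart_log_joints=diag["restart_f"],
        restart_evidences=evidences,
    )


def condition_evidence(fits: list[FitResult]) -> float:
    """Per-subject, per-condition evidence: sum of per-block log evidences."""
    if not fits:
        raise ValueError("at least one block fit is required")
    return float(sum(f.log_evidence for f in fits))
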