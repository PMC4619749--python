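"""Behavioral and model-based performance summaries.

Performance on a block is the money bet on the truly relevant visual feature:
the median over trials is the headline subject statistic, the mean enters the
model-vs-subject correlation.  Model performance evaluates the fitted model's
noise-free response at the posterior mode along the same trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import inversion, perceptual, response
from .inversion import FitResult
from .models import ModelSpec
from .response import TOTAL_MONEY
from .task import Block


@dataclass
class PerformanceRecord:
    subject: int
    condition: str
    block: int
    subject_perf_median: float
    subject_perf_mean: float
    model_perf_mean: float | None = None


def subject_performance(block: Block) -> PerformanceRecord:
    """Median and mean over trials of the money on the relevant feature."""
    feats = block.relevant_features()
    if np.any(feats < 0):
        raise ValueError("block lacks the hidden true-rule labels")
    r = block.responses()
    money = TOTAL_MONEY * r[np.arange(len(feats)), feats]
    return PerformanceRecord(
        subject=block.subject_id,
        condition=block.condition,
        block=block.block_index,
        subject_perf_median=float(np.median(money)),
        subject_perf_mean=float(np.mean(money)),
    )


def _modal_responses(fit: FitResult, block: Block, model: ModelSpec) -> np.ndarray:
    """Noise-free (risk-adjusted power) response per trial at the posterior
    mode; the trial-wise rows of the expected model behavior."""
    perc, resp, mu_f0 = inversion.materialize(fit.params, model)
    T = len(block.trials)
    if model.baseline:
        r = response.softmax(mu_f0)
        return np.tile(r, (T, 1))
    filt = perceptual.run_filter(block, model, perc)
    out = np.empty((T, 3))
    for i, belief in enumerate(filt.beliefs[1:]):
        p = response.feature_probs(belief.mu, model.perceptual)
        out[i] = response.optimal_response(p, resp.theta1)
    return out


def model_expected_performance(fit: FitResult, block: Block, model: ModelSpec) -> float:
    """Mean over trials of the money the modal model response puts on the
    truly relevant feature."""
    feats = block.relevant_features()
    if np.any(feats < 0):
        raise ValueError("block lacks the hidden true-rule labels")
    r = _modal_responses(fit, block, model)
    money = TOTAL_MONEY * r[np.arange(len(feats)), feats]
    return float(np.mean(money))


def performance_correlation(records: list[PerformanceRecord]) -> float:
    """Pearson correlation between mean model and mean subject performance
    across blocks."""
    pairs = [(rec.subject_perf_mean, rec.model_perf_mean) for rec in records
             if rec.model_perf_mean is not None]
    if len(pairs) < 3:
        raise ValueError("at least three paired records are required")
    x, y = np.array(pairs).T
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the performance series")
    return float(np.corrcoef(x, y)[0, 1])


def expected_response_trajectory(
    fit: FitResult,
    block: Block,
    model: ModelSpec,
    rng: np.random.Generator,
    n_samples: int = 10_000,
    level: float = 0.95,
):
    """Per-trial modal response plus the central probability interval of each
    component, estimated from sampled responses at the posterior mode.

    Returns (modal (T,3), lower (T,3), upper (T,3)).
    """
    perc, resp, mu_f0 = inversion.materialize(fit.params, model)
    modal = _modal_responses(fit, block, model)
    T = len(block.trials)
    lo = np.empty((T, 3))
    hi = np.empty((T, 3))
    q = np.array([(1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0])
    if model.baseline:
        dens_seq = [response.response_density(None, None, resp,
                                              baseline_mu_f0=mu_f0)] * T
    else:
        theta = resp
        if model.response == "reduced":
            theta = response.ResponseParams(resp.theta1, resp.theta2, 0.0)
        filt = perceptual.run_filter(block, model, perc)
        dens_seq = [response.response_density(b, model.perceptual, theta)
                    for b in filt.beliefs[1:]]
    for i, dens in enumerate(dens_seq):
        xi = rng.multivariate_normal(np.zeros(3), dens.P, size=n_samples,
                                     method="cholesky")
        z = dens.m[np.newaxis, :] + xi
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        samples = ez / ez.sum(axis=1, keepdims=True)
        lo[i], hi[i] = np.quantile(samples, q, axis=0)
    return modal, lo, hi


def weighted_expected_responses(
    fits: dict[str, FitResult],
    block: Block,
    models: dict[str, ModelSpec],
    weights: dict[str, float],
) -> np.ndarray:
    """Posterior-model-probability-weighted average of per-model modal
    responses (the subject-level mixture used for trajectory figures)."""
    total = np.zeros((len(block.trials), 3))
    wsum = 0.0
    for name, w in weights.items():
        if w <= 0:
            continue
        total += w * _modal_responses(fits[name], block, models[name])
        wsum += w
    if wsum <= 0:
        raise ValueError("weights must have positive mass")
    return total / wsum
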