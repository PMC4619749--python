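"""Probabilistic Wisconsin card sorting task: environments and synthetic cohorts.

Each trial shows a pair of cards; each card carries one exemplar of each of
three binary visual features (color: red/green, motion: left/right, shape:
circle/square).  A hidden rule -- one of the six exemplars -- determines which
card the experimenter picks, except that with probability ``error_rate_true``
the wrong card is chosen.  In the switch condition the rule's feature changes
with probability ``switch_prob`` once a refractory period of ``min_run`` trials
has elapsed since the last change; in the no-switch condition the rule is
fixed.  Subjects respond by splitting $20 across the three features.

Canonical index order: exemplars (red, green, left, right, circle, square),
features (color, motion, shape); exemplars 2j and 2j+1 belong to feature j
(0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import perceptual, response
from .models import ModelSpec
from .perceptual import FEATURE_OF_EXEMPLAR, N_HYPOTHESES, PerceptualParams
from .response import ResponseParams

EXEMPLAR_LABELS = ("red", "green", "left", "right", "circle", "square")
FEATURE_LABELS = ("color", "motion", "shape")

SWITCH = "switch"
NO_SWITCH = "no-switch"


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one experimental condition.

    Defaults follow the study design: 40-trial blocks, three blocks per
    condition; experimenter error rate 0.2 (no-switch) or 0.3 (switch); rule
    changes with probability 0.35 on eligible trials, with an 8-trial
    refractory period after every change (and after the block start).
    """

    n_trials: int = 40
    condition: str = SWITCH
    error_rate_true: float = 0.3
    switch_prob: float = 0.35
    min_run: int = 8
    n_blocks_per_condition: int = 3
    seed: int | None = None
    #: if True, a rule change may re-select the other exemplar of the same
    #: feature; by default the new rule's feature always differs
    allow_same_feature_switch: bool = False

    def __post_init__(self):
        if self.n_trials < 0:
            raise ValueError("n_trials must be nonnegative")
        if self.condition not in (SWITCH, NO_SWITCH):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 < self.error_rate_true < 0.5:
            raise ValueError("error_rate_true must lie in (0, 1/2)")
        if not 0.0 <= self.switch_prob < 1.0:
            raise ValueError("switch_prob must lie in [0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def switch_condition(**kw) -> TaskConfig:
    kw.setdefault("error_rate_true", 0.3)
    kw.setdefault("switch_prob", 0.35)
    return TaskConfig(condition=SWITCH, **kw)


def no_switch_condition(**kw) -> TaskConfig:
    kw.setdefault("error_rate_true", 0.2)
    kw.setdefault("switch_prob", 0.0)
    return TaskConfig(condition=NO_SWITCH, **kw)


@dataclass(frozen=True)
class CardPair:
    """One of the eight stimulus configurations: which exemplar of each
    feature sits on the top card (the bottom card is complementary)."""

    top: tuple[int, int, int]
    bottom: tuple[int, int, int]
    id: int


def enumerate_configurations() -> list[CardPair]:
    """All 2^3 = 8 distinct card pairs."""
    pairs = []
    for i, bits in enumerate(product((0, 1), repeat=3)):
        top = tuple(2 * j + b for j, b in enumerate(bits))
        bottom = tuple(2 * j + (1 - b) for j, b in enumerate(bits))
        pairs.append(CardPair(top=top, bottom=bottom, id=i + 1))
    return pairs


def encode_choice(card_pair: CardPair, chosen_card: str) -> np.ndarray:
    """Binary 6-vector marking the exemplars present on the chosen card."""
    if chosen_card == "top":
        exemplars = card_pair.top
    elif chosen_card == "bottom":
        exemplars = card_pair.bottom
    else:
        raise ValueError(f"chosen_card must be 'top' or 'bottom', got {chosen_card!r}")
    e = np.zeros(6, dtype=int)
    e[list(exemplars)] = 1
    return e


@dataclass
class Trial:
    card_pair: CardPair
    hypothesis: int                 # active rule, exemplar index 0..5
    chosen_card: str                # 'top' or 'bottom'
    experimenter_error: bool
    e: np.ndarray                   # binary 6-vector of chosen exemplars
    response: np.ndarray | None = None

    @property
    def relevant_feature(self) -> int:
        if self.hypothesis < 0:  # hidden labels absent (real data)
            return -1
        return int(FEATURE_OF_EXEMPLAR[self.hypothesis])


@dataclass
class Block:
    config: TaskConfig
    trials: list[Trial]
    block_index: int = 0
    subject_id: int = 0

    @property
    def condition(self) -> str:
        return self.config.condition

    def e_matrix(self) -> np.ndarray:
        return np.array([t.e for t in self.trials])

    def responses(self) -> np.ndarray:
        return np.array([t.response for t in self.trials])

    def hypotheses(self) -> np.ndarray:
        return np.array([t.hypothesis for t in self.trials])

    def relevant_features(self) -> np.ndarray:
        return np.array([t.relevant_feature for t in self.trials])


def generate_rule_sequence(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Hidden rule (hypothesis) per trial.

    The initial rule is uniform over the six exemplars.  The block start counts
    as a change for the refractory period: no switch can occur before trial
    ``min_run`` + 1.  On eligible trials the rule changes with probability
    ``switch_prob``; a change draws uniformly among the four exemplars of the
    other two features (or among all five others if
    ``allow_same_feature_switch``).
    """
    h = int(rng.integers(N_HYPOTHESES))
    seq = np.empty(config.n_trials, dtype=int)
    run = 0  # trials since last change (block start counts as a change)
    for t in range(config.n_trials):
        if run >= config.min_run and rng.random() < config.switch_prob:
            if config.allow_same_feature_switch:
                candidates = [k for k in range(N_HYPOTHESES) if k != h]
            else:
                feat = FEATURE_OF_EXEMPLAR[h]
                candidates = [
                    k for k in range(N_HYPOTHESES) if FEATURE_OF_EXEMPLAR[k] != feat
                ]
            h = int(candidates[rng.integers(len(candidates))])
            run = 0
        seq[t] = h
        run += 1
    return seq


def generate_block(
    config: TaskConfig,
    rng: np.random.Generator,
    block_index: int = 0,
    subject_id: int = 0,
) -> Block:
    """One task realization: rule sequence, stimuli and experimenter choices."""
    configurations = enumerate_configurations()
    rules = generate_rule_sequence(config, rng)
    trials = []
    for h in rules:
        pair = configurations[rng.integers(len(configurations))]
        error = bool(rng.random() < config.error_rate_true)
        on_top = h in pair.top
        chosen = ("top" if on_top else "bottom") if not error else (
            "bottom" if on_top else "top")
        trials.append(
            Trial(
                card_pair=pair,
                hypothesis=int(h),
                chosen_card=chosen,
                experimenter_error=error,
                e=encode_choice(pair, chosen),
            )
        )
    return Block(config=config, trials=trials, block_index=block_index,
                 subject_id=subject_id)


def simulate_agent(
    block: Block,
    model: ModelSpec,
    perc_params: PerceptualParams | None,
    resp_params: ResponseParams,
    rng: np.random.Generator,
    *,
    baseline_mu_f0: np.ndarray | None = None,
) -> Block:
    """Fill in a block's responses by running ``model`` as a generative agent.

    The model's belief filter is run over the block's choice sequence and one
    stochastic allocation is sampled per trial from the model's response
    distribution.  Deterministic given the generator state.
    """
    trials = []
    if model.baseline:
        if baseline_mu_f0 is None:
            raise ValueError("the baseline model needs its mu_f0 vector")
        dens = response.response_density(
            None, None, resp_params, baseline_mu_f0=baseline_mu_f0
        )
        for t in block.trials:
            r = response.sample_response(dens.m, dens.P, rng)
            trials.append(Trial(t.card_pair, t.hypothesis, t.chosen_card,
                                t.experimenter_error, t.e, response=r))
    else:
        filt = perceptual.run_filter(block, model, perc_params)
        theta = resp_params
        if model.response == "reduced":
            theta = ResponseParams(theta.theta1, theta.theta2, 0.0)
        for t, belief in zip(block.trials, filt.beliefs[1:]):
            dens = response.response_density(belief, model.perceptual, theta)
            r = response.sample_response(dens.m, dens.P, rng)
            trials.append(Trial(t.card_pair, t.hypothesis, t.chosen_card,
                                t.experimenter_error, t.e, response=r))
    return Block(config=block.config, trials=trials,
                 block_index=block.block_index, subject_id=block.subject_id)


@dataclass
class CohortSpec:
    """A synthetic cohort: every subject is the same generative model with
    per-subject parameters drawn from ``parameter_sampler`` (a mapping
    parameter name -> (low, high) uniform range on the natural scale)."""

    n_subjects: int
    generating_model: ModelSpec
    parameter_sampler: dict[str, tuple[float, float]]
    seed: int = 0
    n_blocks_per_condition: int = 3
    n_trials: int = 40


def _sample_subject_params(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[PerceptualParams, ResponseParams, dict]:
    drawn = {}
    for name, (lo, hi) in spec.parameter_sampler.items():
        drawn[name] = float(rng.uniform(lo, hi))
    perc_fields = {k: v for k, v in drawn.items()
                   if k in PerceptualParams.__dataclass_fields__}
    resp_fields = {k: v for k, v in drawn.items()
                   if k in ResponseParams.__dataclass_fields__}
    return PerceptualParams(**perc_fields), ResponseParams(**resp_fields), drawn


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Simulate a cohort under the study design.

    Each subject completes ``n_blocks_per_condition`` switch and no-switch
    blocks of ``n_trials`` trials with the design error rates (0.3 / 0.2).
    Returns ``(blocks, ground_truth)`` where ``ground_truth`` maps subject id to
    the generating model name and sampled parameters.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    blocks: list[Block] = []
    truth: dict[int, dict] = {}
    for subj in range(spec.n_subjects):
        perc, resp, drawn = _sample_subject_params(spec, rng)
        truth[subj] = {"model": spec.generating_model.name, "parameters": drawn}
        idx = 0
        for cfg in (
            switch_condition(n_trials=spec.n_trials),
            no_switch_condition(n_trials=spec.n_trials),
        ):
            for _ in range(spec.n_blocks_per_condition):
                env = generate_block(cfg, rng, block_index=idx, subject_id=subj)
                blocks.append(simulate_agent(env, spec.generating_model, perc,
                                             resp, rng))
                idx += 1
    return blocks, truth


# ---------------------------------------------------------------------------
# tabular I/O

def blocks_to_frame(blocks: list[Block]) -> pd.DataFrame:
    """One row per trial; hidden columns (true rule, experimenter error) are
    included when available, as for synthetic data."""
    rows = []
    for b in blocks:
        for i, t in enumerate(b.trials):
            row = {
                "subject": b.subject_id,
                "condition": b.condition,
                "block": b.block_index,
                "trial": i,
                "top_color": EXEMPLAR_LABELS[t.card_pair.top[0]],
                "top_motion": EXEMPLAR_LABELS[t.card_pair.top[1]],
                "top_shape": EXEMPLAR_LABELS[t.card_pair.top[2]],
                "chosen_card": t.chosen_card,
                "true_hypothesis": EXEMPLAR_LABELS[t.hypothesis],
                "experimenter_error": int(t.experimenter_error),
            }
            for k, lab in enumerate(EXEMPLAR_LABELS):
                row[f"e_{lab}"] = int(t.e[k])
            if t.response is not None:
                for j, lab in enumerate(FEATURE_LABELS):
                    row[f"r_{lab}"] = float(t.response[j])
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_blocks(df: pd.DataFrame) -> list[Block]:
    """Rebuild blocks from a trial table (inverse of :func:`blocks_to_frame`).

    Hidden columns are optional, matching real data exports; missing ones are
    filled with placeholders (hypothesis -1) usable for fitting but not for
    performance metrics.
    """
    configurations = {p.top: p for p in enumerate_configurations()}
    ex_index = {lab: k for k, lab in enumerate(EXEMPLAR_LABELS)}
    blocks = []
    for (subj, cond, bidx), grp in df.groupby(
        ["subject", "condition", "block"], sort=True
    ):
        grp = grp.sort_values("trial")
        cfg = (switch_condition(n_trials=len(grp)) if cond == SWITCH
               else no_switch_condition(n_trials=len(grp)))
        trials = []
        for _, row in grp.iterrows():
            top = (ex_index[row["top_color"]], ex_index[row["top_motion"]],
                   ex_index[row["top_shape"]])
            pair = configurations[top]
            h = ex_index.get(row.get("true_hypothesis"), -1) \
                if "true_hypothesis" in row else -1
            resp = None
            if "r_color" in row and not pd.isna(row["r_color"]):
                resp = np.array([row[f"r_{lab}"] for lab in FEATURE_LABELS])
            trials.append(
                Trial(
                    card_pair=pair,
                    hypothesis=int(h),
                    chosen_card=row["chosen_card"],
                    experimenter_error=bool(row.get("experimenter_error", False)),
                    e=encode_choice(pair, row["chosen_card"]),
                    response=resp,
                )
            )
        blocks.append(Block(config=cfg, trials=trials, block_index=int(bidx),
                            subject_id=int(subj)))
    return blocks


def save_cohort(blocks, truth, data_path, truth_path=None) -> None:
    blocks_to_frame(blocks).to_csv(data_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump({str(k): v for k, v in truth.items()}, fh, indent=1)


def load_cohort(data_path) -> list[Block]:
    return frame_to_blocks(pd.read_csv(data_path))
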