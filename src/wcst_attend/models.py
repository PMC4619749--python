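"""The roster of 17 behavioral models and the family partitions used for
family-wise model comparison.

A behavioral model pairs a perceptual variant (which belief filter) with a
response variant (how beliefs become money allocations):

* ``BM`` -- baseline: constant belief, constant noise; free parameters are the
  3-vector response mean mu_f0 and the extra variance theta3.
* Bayesian perceptual models ``B_<s>^<r>``: structures d, w1, w2, w3 pair with
  both the full (``f``, theta3 free) and reduced (``r``, theta3 = 0) response
  models; the reduced structures rw, rd only with the reduced response model,
  since their feature-level uncertainty is not dynamic.
* Non-Bayesian models ``NB_<s>^r``: all six structures, reduced response only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .perceptual import FULL_STRUCTURES, PerceptualVariant, REDUCED_STRUCTURES

RESPONSE_VARIANTS = ("full", "reduced")


@dataclass(frozen=True)
class ModelSpec:
    """One behavioral model: perceptual structure x response variant."""

    perceptual: PerceptualVariant | None
    response: str = "reduced"
    baseline: bool = False

    def __post_init__(self):
        if self.baseline:
            if self.perceptual is not None:
                raise ValueError("the baseline model has no perceptual variant")
            return
        if self.response not in RESPONSE_VARIANTS:
            raise ValueError(f"unknown response variant {self.response!r}")
        if self.response == "full" and not (
            self.perceptual.bayesian and not self.perceptual.reduced
        ):
            raise ValueError(
                "the full response model requires a Bayesian full-hierarchy "
                "perceptual model (dynamic feature-level uncertainty)"
            )

    @property
    def name(self) -> str:
        if self.baseline:
            return "BM"
        prefix = "B" if self.perceptual.bayesian else "NB"
        suffix = "f" if self.response == "full" else "r"
        return f"{prefix}_{self.perceptual.structure}^{suffix}"

    def __str__(self) -> str:
        return self.name


def baseline_model() -> ModelSpec:
    return ModelSpec(perceptual=None, baseline=True)


def model_roster() -> list[ModelSpec]:
    """All 17 admissible models, in canonical order (BM first, then Bayesian,
    then non-Bayesian; full-hierarchy structures before reduced ones)."""
    roster = [baseline_model()]
    for s in FULL_STRUCTURES:
        for r in ("full", "reduced"):
            roster.append(ModelSpec(PerceptualVariant(s, bayesian=True), r))
    for s in REDUCED_STRUCTURES:
        roster.append(ModelSpec(PerceptualVariant(s, bayesian=True), "reduced"))
    for s in FULL_STRUCTURES + REDUCED_STRUCTURES:
        roster.append(ModelSpec(PerceptualVariant(s, bayesian=False), "reduced"))
    return roster


def model_by_name(name: str) -> ModelSpec:
    for m in model_roster():
        if m.name == name:
            return m
    raise KeyError(f"unknown model {name!r}")


def _names(models) -> list[str]:
    return [m.name for m in models]


def family_partitions() -> dict[str, dict[str, list[str]]]:
    """The four family-wise partitions of the 17-model roster.

    * bayesian: baseline vs non-Bayesian vs Bayesian updating
    * hierarchy: reduced (exemplar-level only) vs full perceptual hierarchy
    * structure: structure-free (diffusive) vs structured (WTA inhibition)
    * response: reduced vs full response model
    """
    roster = model_roster()
    non_bm = [m for m in roster if not m.baseline]

    def sel(pred):
        return _names(m for m in non_bm if pred(m))

    bayesian = {
        "BM": ["BM"],
        "NB": sel(lambda m: not m.perceptual.bayesian),
        "B": sel(lambda m: m.perceptual.bayesian),
    }
    hierarchy = {
        "BM": ["BM"],
        "RP": sel(lambda m: m.perceptual.reduced),
        "FP": sel(lambda m: not m.perceptual.reduced),
    }
    structure = {
        "BM": ["BM"],
        "SFM": sel(lambda m: m.perceptual.structure in ("d", "rd")),
        "SM": sel(lambda m: m.perceptual.structure in ("w1", "w2", "w3", "rw")),
    }
    response = {
        "RR": ["BM"] + sel(lambda m: m.response == "reduced"),
        "FR": sel(lambda m: m.response == "full"),
    }
    return {
        "bayesian": bayesian,
        "hierarchy": hierarchy,
        "structure": structure,
        "response": response,
    }
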