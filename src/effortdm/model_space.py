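"""Subjective-value model space for binary accept/reject effort decisions.

The family combines a cost function over effort with a softmax choice rule.
An offer pairs an effort level E (1-4) with a reward level R (2-5 points);
both are standardized to (0, 1] before entering the model. The subjective
value of accepting is

    SV = beta_R * r - cost(e)

where ``cost`` is linear (beta_E * e), parabolic (beta_E * e^2) or
exponential (beta_E * (exp(e) - 1)), and the acceptance probability is

    p(accept) = 1 / (1 + exp(-(alpha + SV)))

with acceptance bias ``alpha`` acting as an intercept. Nine models arise
from crossing the three cost kinds with three parameter configurations:
beta_E only, beta_E + beta_R, and the full set alpha + beta_R + beta_E.
Excluded parameters are fixed (alpha = 0, beta_R = 1), so the full model
nests the reduced ones exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "EFFORT_LEVEL_MAX",
    "REWARD_POINTS_MAX",
    "ParameterSet",
    "CostFunction",
    "ModelSpec",
    "StandardizedOffer",
    "standardize_effort",
    "standardize_reward",
    "subjective_value",
    "acceptance_probability",
    "trial_loglik",
    "session_loglik",
    "model_registry",
    "get_model",
]

EFFORT_LEVEL_MAX = 4
REWARD_POINTS_MAX = 5

_COST_KINDS = ("linear", "parabolic", "exponential")
_CONFIG_FREE = {
    "minimal": frozenset({"beta_E"}),
    "reward": frozenset({"beta_E", "beta_R"}),
    "full": frozenset({"beta_E", "beta_R", "alpha"}),
}


@dataclass(frozen=True)
class ParameterSet:
    """Decision parameters on the natural scale.

    alpha may take any real value; beta_R and beta_E must be non-negative
    (positive for any discounting to occur). Models that exclude a
    parameter substitute alpha = 0 and beta_R = 1.
    """

    alpha: float = 0.0
    beta_R: float = 1.0
    beta_E: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_R < 0 or self.beta_E < 0:
            raise ValueError(
                f"sensitivities must be non-negative, got "
                f"beta_R={self.beta_R}, beta_E={self.beta_E}"
            )


@dataclass(frozen=True)
class CostFunction:
    """Effort-cost transform; ``kind`` is linear, parabolic or exponential."""

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _COST_KINDS:
            raise ValueError(f"unknown cost kind {self.kind!r}; one of {_COST_KINDS}")

    def effort_transform(self, e):
        """The effort term multiplying beta_E; vectorized over ``e``."""
        e = np.asarray(e, dtype=float)
        if self.kind == "linear":
            return e
        if self.kind == "parabolic":
            return e**2
        return np.expm1(e)

    def __call__(self, e, beta_E: float):
        return beta_E * self.effort_transform(e)


@dataclass(frozen=True)
class StandardizedOffer:
    """Offer mapped to the unit scale: e = E/4 in (0,1], r = R/5 in (0,1]."""

    e: float
    r: float

    def __post_init__(self) -> None:
        if not (0 < self.e <= 1 and 0 < self.r <= 1):
            raise ValueError(f"standardized offer out of (0,1]: e={self.e}, r={self.r}")

    @classmethod
    def from_levels(cls, effort_level: int, reward_points: int) -> "StandardizedOffer":
        return cls(
            e=standardize_effort(effort_level), r=standardize_reward(reward_points)
        )


def standardize_effort(effort_level):
    """Map effort level 1-4 to e = level/4."""
    return np.asarray(effort_level, dtype=float) / EFFORT_LEVEL_MAX


def standardize_reward(reward_points):
    """Map reward points 2-5 to r = points/5."""
    return np.asarray(reward_points, dtype=float) / REWARD_POINTS_MAX


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a cost function plus a set of free parameters."""

    name: str
    cost: CostFunction
    free_params: frozenset = field(default_factory=lambda: frozenset({"beta_E"}))
    is_reference_winner: bool = False

    def __post_init__(self) -> None:
        if "beta_E" not in self.free_params:
            raise ValueError("beta_E is free in every model")
        unknown = self.free_params - {"alpha", "beta_R", "beta_E"}
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def constrain(self, params: ParameterSet) -> ParameterSet:
        """Substitute the fixed values for excluded parameters."""
        return ParameterSet(
            alpha=params.alpha if "alpha" in self.free_params else 0.0,
            beta_R=params.beta_R if "beta_R" in self.free_params else 1.0,
            beta_E=params.beta_E,
        )


def subjective_value(offer: StandardizedOffer, params: ParameterSet,
                     cost: CostFunction) -> float:
    """SV = beta_R * r - cost(e), on the standardized offer scale."""
    return float(params.beta_R * offer.r - cost(offer.e, params.beta_E))


def acceptance_probability(sv, alpha=0.0):
    """Softmax (logistic) choice rule p = 1 / (1 + exp(-(alpha + sv))).

    Numerically stable for arbitrarily large |alpha + sv| (evaluates the
    logistic through scipy's expit).
    """
    from scipy.special import expit

    out = expit(np.asarray(sv, dtype=float) + np.asarray(alpha, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def _decision_to_binary(decision) -> int:
    if decision in (1, True, "accept"):
        return 1
    if decision in (0, False, "reject"):
        return 0
    raise ValueError(f"decision must be 'accept' or 'reject', got {decision!r}")


def trial_loglik(trial, params: ParameterSet, model: ModelSpec) -> float:
    """Bernoulli log-likelihood of one observed decision under ``model``.

    ``trial`` needs ``offer`` (with effort_level / reward_points) and
    ``decision`` attributes, or can be a mapping with ``effort_level``,
    ``reward`` and ``decision`` keys.
    """
    p = params if isinstance(params, ParameterSet) else ParameterSet(*params)
    p = model.constrain(p)
    if hasattr(trial, "offer"):
        level, points = trial.offer.effort_level, trial.offer.reward_points
        decision = trial.decision
    else:
        level, points = trial["effort_level"], trial["reward"]
        decision = trial["decision"]
    offer = StandardizedOffer.from_levels(level, points)
    sv = subjective_value(offer, p, model.cost)
    y = _decision_to_binary(decision)
    # log p / log(1-p) via the stable log-sigmoid: log expit(x) = -log1p(e^-x)
    x = p.alpha + sv
    sign = 1.0 if y == 1 else -1.0
    return float(-np.logaddexp(0.0, -sign * x))


def session_loglik(trials: Iterable, params: ParameterSet, model: ModelSpec) -> float:
    """Sum of per-trial log-likelihoods over a session."""
    return float(sum(trial_loglik(t, params, model) for t in trials))


def model_registry() -> list[ModelSpec]:
    """The nine candidate models: 3 parameter configurations x 3 cost kinds.

    The three-parameter parabolic model ("full_parabolic") is flagged as the
    reference winner of the original model comparison.
    """
    registry = []
    for config, free in _CONFIG_FREE.items():
        for kind in _COST_KINDS:
            name = f"{config}_{kind}"
            registry.append(
                ModelSpec(
                    name=name,
                    cost=CostFunction(kind),
                    free_params=free,
                    is_reference_winner=(name == "full_parabolic"),
                )
            )
    return registry


_ALIAS_KINDS = {"exp": "exponential", "quad": "parabolic"}


def get_model(name: str) -> ModelSpec:
    """Look up a model by name; tolerates reversed token order and 'exp'."""
    registry = {m.name: m for m in model_registry()}
    if name in registry:
        return registry[name]
    tokens = name.split("_")
    tokens = [_ALIAS_KINDS.get(t, t) for t in tokens]
    for candidate in ("_".join(tokens), "_".join(reversed(tokens))):
        if candidate in registry:
            return registry[candidate]
    raise KeyError(f"unknown model {name!r}; known: {sorted(registry)}")
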