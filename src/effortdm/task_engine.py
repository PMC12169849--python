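"""Seeded simulator of the adaptive effort-expenditure task.

The task: after a clicking-capacity calibration (three 10 s repetitions,
capacity = mean of repetitions 2 and 3), an agent faces 64 binary offers,
each pairing an effort level (1-4: clicking at 30/50/70/90% of capacity for
8/11/14/17 s) with a reward (2-5 points). Offers are scheduled by 16
interleaved staircases whose start offers enumerate the full 4x4
effort x reward grid; accepting makes that staircase's next offer harder
(effort +1 or reward -1), rejecting makes it easier (effort -1 or
reward +1). Rejected offers always pay 1 point; accepted offers pay the
reward if the clicking challenge is met and 0 otherwise.

Decisions are drawn from a :mod:`effortdm.model_space` model; challenge
outcomes from a Gaussian motor-noise model of clicking rate tuned so that
accepted challenges succeed in the high-90% range, matching the regime the
task is designed for (effort levels feasible for everyone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import math

import numpy as np

from .model_space import (
    ModelSpec,
    ParameterSet,
    StandardizedOffer,
    acceptance_probability,
    subjective_value,
)

__all__ = [
    "EFFORT_LEVELS",
    "CalibrationResult",
    "EffortLevelSpec",
    "Offer",
    "Staircase",
    "TrialRecord",
    "MotorModel",
    "Agent",
    "SessionConfig",
    "SessionRecord",
    "calibrate_capacity",
    "required_clicks",
    "init_staircases",
    "staircase_update",
    "simulate_challenge_outcome",
    "run_session",
]

MIN_CAPACITY = 7  # calibration scores below this are excluded downstream
REJECT_POINTS = 1


@dataclass(frozen=True)
class EffortLevelSpec:
    """One of the four effort levels: a capacity fraction held for a duration."""

    level: int
    fraction_of_capacity: float
    duration: float  # seconds

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 4:
            raise ValueError(f"effort level must be 1-4, got {self.level}")


#: Levels 1-4: 30% of capacity for 8 s up to 90% for 17 s.
EFFORT_LEVELS: tuple[EffortLevelSpec, ...] = (
    EffortLevelSpec(1, 0.30, 8.0),
    EffortLevelSpec(2, 0.50, 11.0),
    EffortLevelSpec(3, 0.70, 14.0),
    EffortLevelSpec(4, 0.90, 17.0),
)


def effort_level_spec(level: int) -> EffortLevelSpec:
    try:
        spec = EFFORT_LEVELS[int(level) - 1]
    except (IndexError, ValueError):
        raise ValueError(f"unknown effort level {level!r}") from None
    if spec.level != level:
        raise ValueError(f"unknown effort level {level!r}")
    return spec


@dataclass(frozen=True)
class CalibrationResult:
    """Three 10 s clicking repetitions; capacity = mean of reps 2 and 3."""

    rep_clicks: tuple[int, int, int]
    capacity: float
    post_task_clicks: Optional[int] = None

    @property
    def spread(self) -> int:
        """Max minus min repetition count (compliance screening)."""
        return max(self.rep_clicks) - min(self.rep_clicks)

    @property
    def pre_post_change(self) -> Optional[float]:
        if self.post_task_clicks is None:
            return None
        return self.capacity - self.post_task_clicks


def calibrate_capacity(rep_clicks: Sequence[int],
                       post_task_clicks: Optional[int] = None) -> CalibrationResult:
    """Compute clicking capacity from three calibration repetitions.

    The first repetition is treated as practice and ignored; capacity is the
    mean of repetitions 2 and 3 (clicks per 10 s).
    """
    reps = tuple(rep_clicks)
    if len(reps) != 3:
        raise ValueError(f"exactly three calibration repetitions required, got {len(reps)}")
    if any(r < 0 for r in reps):
        raise ValueError(f"click counts must be non-negative, got {reps}")
    capacity = (reps[1] + reps[2]) / 2.0
    return CalibrationResult(rep_clicks=reps, capacity=capacity,
                             post_task_clicks=post_task_clicks)


def required_clicks(level, capacity: float, rounding: str = "ceil") -> int:
    """Clicks needed to pass a challenge at ``level`` given ``capacity``.

    The target is fraction x (capacity/10 clicks-per-second) x duration,
    rounded per ``rounding`` ("ceil" default, "floor", or "round"), with a
    floor of one click.
    """
    if capacity < MIN_CAPACITY:
        raise ValueError(f"capacity {capacity} below task minimum {MIN_CAPACITY}")
    spec = level if isinstance(level, EffortLevelSpec) else effort_level_spec(level)
    raw = spec.fraction_of_capacity * (capacity / 10.0) * spec.duration
    if rounding == "ceil":
        n = math.ceil(raw)
    elif rounding == "floor":
        n = math.floor(raw)
    elif rounding == "round":
        n = round(raw)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return max(1, int(n))


@dataclass(frozen=True)
class Offer:
    """One effort x reward challenge: effort level 1-4, reward 2-5 points."""

    effort_level: int
    reward_points: int

    def __post_init__(self) -> None:
        if not 1 <= self.effort_level <= 4:
            raise ValueError(f"effort level out of 1-4: {self.effort_level}")
        if not 2 <= self.reward_points <= 5:
            raise ValueError(f"reward points out of 2-5: {self.reward_points}")

    def standardized(self) -> StandardizedOffer:
        return StandardizedOffer.from_levels(self.effort_level, self.reward_points)


def offer_grid() -> list[Offer]:
    """All 16 offers of the 4x4 effort x reward grid."""
    return [Offer(e, r) for e in range(1, 5) for r in range(2, 6)]


@dataclass
class Staircase:
    id: int
    start_offer: Offer
    current_offer: Offer
    visit_count: int = 0


def init_staircases(seed=None) -> list[Staircase]:
    """Sixteen staircases whose start offers enumerate the 4x4 grid once.

    The seed only shuffles which grid cell is assigned to which staircase
    id; the set of start offers is always the full grid.
    """
    rng = np.random.default_rng(seed)
    offers = offer_grid()
    rng.shuffle(offers)
    return [
        Staircase(id=i + 1, start_offer=o, current_offer=o)
        for i, o in enumerate(offers)
    ]


def staircase_update(offer: Offer, decision, rng) -> Offer:
    """Next offer on a staircase after ``decision`` on ``offer``.

    Acceptance makes the staircase harder: effort +1 or reward -1 (one
    dimension, chosen uniformly when both moves stay on the grid).
    Rejection makes it easier: effort -1 or reward +1. At a corner where
    neither move is feasible the offer is unchanged.
    """
    accept = decision in (1, True, "accept")
    if not accept and decision not in (0, False, "reject"):
        raise ValueError(f"decision must be accept/reject, got {decision!r}")
    if accept:
        moves = []
        if offer.effort_level < 4:
            moves.append(Offer(offer.effort_level + 1, offer.reward_points))
        if offer.reward_points > 2:
            moves.append(Offer(offer.effort_level, offer.reward_points - 1))
    else:
        moves = []
        if offer.effort_level > 1:
            moves.append(Offer(offer.effort_level - 1, offer.reward_points))
        if offer.reward_points < 5:
            moves.append(Offer(offer.effort_level, offer.reward_points + 1))
    if not moves:
        return offer
    if len(moves) == 1:
        return moves[0]
    return moves[int(rng.integers(len(moves)))]


@dataclass(frozen=True)
class MotorModel:
    """Gaussian clicking model: rate in clicks/s with trial-to-trial noise.

    ``fatigue_drift`` is the expected pre-to-post capacity change over the
    session (clicks per 10 s window), applied only to the simulated
    post-task calibration repetition.
    """

    true_rate: float
    rate_sd: float = 0.8
    fatigue_drift: float = -2.3

    def __post_init__(self) -> None:
        if self.true_rate <= 0:
            raise ValueError(f"true_rate must be positive, got {self.true_rate}")
        if self.rate_sd < 0:
            raise ValueError(f"rate_sd must be non-negative, got {self.rate_sd}")

    @classmethod
    def from_capacity(cls, capacity: float, rate_scale: float = 0.97,
                      rate_sd: float = 0.8, fatigue_drift: float = -2.3) -> "MotorModel":
        """Motor model whose sustained rate is ``rate_scale`` x the
        calibrated burst rate (capacity/10 clicks per second)."""
        return cls(true_rate=rate_scale * capacity / 10.0, rate_sd=rate_sd,
                   fatigue_drift=fatigue_drift)


def simulate_challenge_outcome(agent, level, capacity: float, rng,
                               rounding: str = "ceil"):
    """Simulate clicking through one accepted challenge.

    Clicks made ~ round(Normal(rate x duration, rate_sd x sqrt(duration)))
    truncated at zero; success means meeting the required click count.
    Returns ``(success, clicks_made)``.
    """
    motor: MotorModel = agent.motor if hasattr(agent, "motor") else agent
    spec = level if isinstance(level, EffortLevelSpec) else effort_level_spec(level)
    needed = required_clicks(spec, capacity, rounding=rounding)
    mean = motor.true_rate * spec.duration
    sd = motor.rate_sd * math.sqrt(spec.duration)
    clicks = int(round(rng.normal(mean, sd))) if sd > 0 else int(round(mean))
    clicks = max(0, clicks)
    return clicks >= needed, clicks


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    trial_index: int  # 1-64
    block: int  # 1-4
    staircase_id: int
    offer: Offer
    decision: str  # "accept" | "reject"
    challenge_success: Optional[bool]
    clicks_made: Optional[int]
    points_earned: int


@dataclass(frozen=True)
class Agent:
    """A simulated participant: decision parameters plus motor capability."""

    subject_id: str
    params: ParameterSet
    motor: MotorModel
    calibration: CalibrationResult

    @property
    def capacity(self) -> float:
        return self.calibration.capacity


@dataclass(frozen=True)
class SessionConfig:
    n_blocks: int = 4
    trials_per_block: int = 16
    rounding: str = "ceil"
    capacity_override: Optional[float] = None  # practice-phase re-adjustment hook

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.trials_per_block != 16:
            raise ValueError("session config requires 16-trial blocks over >=1 block")


@dataclass
class SessionRecord:
    subject_id: str
    seed: int
    model_name: str
    trials: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def acceptance_proportion(self) -> float:
        return float(np.mean([t.decision == "accept" for t in self.trials]))


def make_agent(subject_id: str, params: ParameterSet, capacity_clicks: float = 60.0,
               rng=None, rate_scale: float = 0.97, rate_sd: float = 0.8) -> Agent:
    """Convenience constructor: calibration reps drawn around ``capacity_clicks``."""
    rng = np.random.default_rng(rng)
    reps = tuple(
        max(0, int(round(rng.normal(capacity_clicks, 2.0)))) for _ in range(3)
    )
    calib = calibrate_capacity(reps)
    motor = MotorModel.from_capacity(calib.capacity, rate_scale=rate_scale,
                                     rate_sd=rate_sd)
    return Agent(subject_id=subject_id, params=params, motor=motor, calibration=calib)


def run_session(agent: Agent, model: ModelSpec, config: SessionConfig = None,
                seed=None) -> SessionRecord:
    """Simulate one full session: 64 trials in 4 blocks of 16.

    Each block presents every staircase exactly once in seeded-random
    order; decisions are Bernoulli draws from the agent's acceptance
    probability under ``model``; accepted offers resolve a clicking
    challenge. Deterministic given (agent, model, config, seed).
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(seed)
    capacity = (config.capacity_override
                if config.capacity_override is not None else agent.capacity)
    if capacity < MIN_CAPACITY:
        raise ValueError(
            f"capacity {capacity} below the task minimum of {MIN_CAPACITY} clicks")
    params = model.constrain(agent.params)
    staircases = init_staircases(rng.integers(2**31))
    record = SessionRecord(subject_id=agent.subject_id,
                           seed=-1 if seed is None else int(seed),
                           model_name=model.name)
    trial_index = 0
    for block in range(1, config.n_blocks + 1):
        order = rng.permutation(len(staircases))
        for idx in order:
            sc = staircases[idx]
            trial_index += 1
            offer = sc.current_offer
            sv = subjective_value(offer.standardized(), params, model.cost)
            p_accept = acceptance_probability(sv, params.alpha)
            accept = rng.random() < p_accept
            if accept:
                success, clicks = simulate_challenge_outcome(
                    agent, offer.effort_level, capacity, rng,
                    rounding=config.rounding)
                points = offer.reward_points if success else 0
                decision = "accept"
            else:
                success, clicks = None, None
                points = REJECT_POINTS
                decision = "reject"
            record.trials.append(TrialRecord(
                subject_id=agent.subject_id, trial_index=trial_index,
                block=block, staircase_id=sc.id, offer=offer,
                decision=decision, challenge_success=success,
                clicks_made=clicks, points_earned=points))
            sc.current_offer = staircase_update(offer, decision, rng)
            sc.visit_count += 1
    return record


TRIAL_COLUMNS = ["subject_id", "trial", "block", "staircase", "effort_level",
                 "reward", "decision", "success", "clicks", "points"]


def sessions_to_frame(sessions) -> "pd.DataFrame":
    """Flatten SessionRecords into the canonical trial-log DataFrame.

    Columns: subject_id, trial, block, staircase, effort_level, reward,
    decision, success, clicks, points. ``success``/``clicks`` are empty for
    rejected trials.
    """
    import pandas as pd

    if hasattr(sessions, "trials"):
        sessions = [sessions]
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append((t.subject_id, t.trial_index, t.block, t.staircase_id,
                         t.offer.effort_level, t.offer.reward_points, t.decision,
                         t.challenge_success, t.clicks_made, t.points_earned))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_post_task_calibration(agent: Agent, rng) -> CalibrationResult:
    """Repeat one calibration trial after the session (fatigue monitoring)."""
    rng = np.random.default_rng(rng)
    post = max(0, int(round(rng.normal(
        agent.capacity + agent.motor.fatigue_drift, 3.0))))
    return replace(agent.calibration, post_task_clicks=post)
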