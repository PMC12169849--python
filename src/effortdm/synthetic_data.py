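"""Synthetic agent populations with the covariate structure the analyses assume.

The generator produces (a) agents whose decision parameters
(alpha, beta_R, beta_E) are drawn from group distributions, and (b) a
per-subject covariate table of questionnaire sum scores and demographics.
Three generative effects tie covariates to parameters:

* a one-dimensional latent motivational-symptom factor that loads on the
  anhedonia/apathy questionnaires (SHAPS positively; DARS and AES are kept
  on their native scales where higher = less severe, and flipped later in
  the analysis layer) and *negatively* on the acceptance bias alpha;
* a chronotype main effect: late chronotypes have a lower alpha and a
  higher reward sensitivity beta_R than early chronotypes;
* a chronotype-by-time-of-day synchrony effect on alpha: late chronotypes
  tested in the evening recover part of the deficit (positive
  late x evening interaction).

All generative truths (parameters, factor scores, chronotype class) are
stored in the covariate table so downstream recovery can be asserted.
Outputs are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import task_engine
from .model_space import ModelSpec, ParameterSet, get_model

__all__ = [
    "InstrumentSpec",
    "INSTRUMENTS",
    "PopulationConfig",
    "generate_population",
    "generate_sessions",
    "generate_testretest",
    "null_config",
    "paper_like_config",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """Scoring range and population calibration of one questionnaire."""

    name: str
    floor: float
    ceiling: float
    mean: float
    sd: float
    #: correlation of the score with the latent symptom factor; negative for
    #: instruments whose native direction is "higher = less severe"
    factor_loading: float


#: Instrument calibrations. Means/SDs follow the general-population sample
#: this package emulates (e.g. SHAPS 9.15 +/- 6.28 on its 0-36 sum scale).
INSTRUMENTS: dict[str, InstrumentSpec] = {
    "shaps": InstrumentSpec("shaps", 0, 36, 9.15, 6.28, +0.70),
    "dars": InstrumentSpec("dars", 0, 68, 53.5, 9.4, -0.70),
    "aes": InstrumentSpec("aes", 18, 72, 53.5, 10.0, -0.70),
    "meq": InstrumentSpec("meq", 16, 86, 50.0, 10.0, 0.0),
    "bmi": InstrumentSpec("bmi", 14, 55, 26.5, 5.2, 0.0),
    "findrisc": InstrumentSpec("findrisc", 0, 26, 7.0, 4.0, 0.0),
}


@dataclass(frozen=True)
class ChronotypeEffects:
    """Generative circadian effects on decision parameters (natural scale)."""

    delta_beta_R_late: float = 1.7  # late > early reward sensitivity
    delta_alpha_late: float = -0.8  # late chronotype lowers acceptance bias
    delta_alpha_synchrony: float = 1.4  # late x evening recovers alpha


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 200
    # group distributions of decision parameters (natural scale), calibrated
    # so simulated cohorts land in the published acceptance regime
    # (subject-mean ~0.77, between-subject SD ~0.15)
    mean_alpha: float = 1.4
    sd_alpha: float = 1.0
    mean_beta_R: float = 2.0
    sd_beta_R: float = 0.8
    mean_beta_E: float = 2.0
    sd_beta_E: float = 0.8
    #: loading of the latent symptom factor on alpha; negative = more
    #: severe symptoms, lower acceptance bias
    psych_effect: float = -0.18
    chronotype_effects: ChronotypeEffects = field(default_factory=ChronotypeEffects)
    #: early / intermediate / late proportions
    chronotype_proportions: tuple[float, float, float] = (0.10, 0.80, 0.10)
    morning_testing_proportion: float = 0.5
    #: residual questionnaire noise as a fraction of the instrument SD
    questionnaire_noise: float = 0.6
    mean_age: float = 45.0
    sd_age: float = 15.0
    female_proportion: float = 0.55
    mean_capacity: float = 60.0
    sd_capacity: float = 16.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        props = self.chronotype_proportions
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(
                f"chronotype proportions must be non-negative and sum to 1, "
                f"got {props}")
        if not 0 <= self.morning_testing_proportion <= 1:
            raise ValueError("morning_testing_proportion must be in [0, 1]")
        if min(self.sd_alpha, self.sd_beta_R, self.sd_beta_E) < 0:
            raise ValueError("group SDs must be non-negative")


def null_config(n_subjects: int = 200, seed=None) -> PopulationConfig:
    """Cohort with no covariate structure: parameters are pure group noise."""
    return PopulationConfig(
        n_subjects=n_subjects, psych_effect=0.0,
        chronotype_effects=ChronotypeEffects(0.0, 0.0, 0.0), seed=seed)


def paper_like_config(n_subjects: int = 200, seed=None) -> PopulationConfig:
    """The default effect structure (symptom factor + circadian effects)."""
    return PopulationConfig(n_subjects=n_subjects, seed=seed)


def _positive_lognormal(mean, sd, size, rng):
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _questionnaire(spec: InstrumentSpec, factor, noise_frac, rng):
    """Score = calibrated mean + SD * (loading*factor + residual), clipped to
    the instrument range. Returns (scores, n_clipped)."""
    lam = spec.factor_loading
    resid_sd = np.sqrt(max(0.0, 1.0 - lam**2)) * max(noise_frac, 1e-12)
    # renormalize so the marginal SD stays at the calibrated value
    scale = np.sqrt(lam**2 + resid_sd**2)
    z = (lam * factor + resid_sd * rng.standard_normal(factor.size)) / scale
    raw = spec.mean + spec.sd * z
    clipped = np.clip(raw, spec.floor, spec.ceiling)
    n_clipped = int(np.sum(raw != clipped))
    return np.round(clipped).astype(int), n_clipped


def _chronotype_covariates(classes, rng):
    """MEQ sums and free-day mid-sleep times consistent with each class.

    Early: MEQ > 58 and mid-sleep before 02:30; late: MEQ < 42 and
    mid-sleep after 05:30; intermediate strictly inside both boundaries,
    so a threshold classifier recovers the class exactly.
    """
    n = classes.size
    meq = np.empty(n, dtype=int)
    midsleep = np.empty(n)
    for i, c in enumerate(classes):
        if c == "early":
            meq[i] = rng.integers(59, 80)
            midsleep[i] = rng.uniform(0.8, 2.4)
        elif c == "late":
            meq[i] = rng.integers(20, 42)
            midsleep[i] = rng.uniform(5.6, 7.8)
        else:
            meq[i] = rng.integers(43, 58)
            midsleep[i] = rng.uniform(2.8, 5.2)
    return meq, midsleep


def _hours_to_clock(hours: np.ndarray) -> list[str]:
    h = (np.asarray(hours) % 24.0)
    out = []
    for v in h:
        hh = int(v)
        mm = int(round((v - hh) * 60))
        if mm == 60:
            hh, mm = hh + 1, 0
        out.append(f"{hh:02d}:{mm:02d}")
    return out


def generate_population(config: PopulationConfig = PopulationConfig()):
    """Draw a cohort of agents plus their covariate table.

    Returns ``(agents, covariates)`` where ``agents`` is a list of
    :class:`effortdm.task_engine.Agent` and ``covariates`` a DataFrame with
    questionnaire sums, demographics, testing window, and the generative
    truths (``true_alpha``, ``true_beta_R``, ``true_beta_E``,
    ``true_factor``, ``true_chronotype``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    eff = config.chronotype_effects

    factor = rng.standard_normal(n)
    classes = rng.choice(np.array(["early", "intermediate", "late"]),
                         size=n, p=config.chronotype_proportions)
    early = (classes == "early").astype(float)
    late = (classes == "late").astype(float)
    morning = rng.random(n) < config.morning_testing_proportion
    evening = (~morning).astype(float)

    alpha = (config.mean_alpha
             + config.psych_effect * factor
             + eff.delta_alpha_late * late
             + eff.delta_alpha_synchrony * late * evening
             + config.sd_alpha * rng.standard_normal(n))
    beta_R = (_positive_lognormal(config.mean_beta_R, config.sd_beta_R, n, rng)
              + eff.delta_beta_R_late * late)
    beta_E = _positive_lognormal(config.mean_beta_E, config.sd_beta_E, n, rng)

    q_scores, clip_counts = {}, {}
    for key in ("shaps", "dars", "aes"):
        q_scores[key], clip_counts[key] = _questionnaire(
            INSTRUMENTS[key], factor, config.questionnaire_noise, rng)
    meq, midsleep = _chronotype_covariates(classes, rng)
    bmi_raw = np.clip(rng.normal(INSTRUMENTS["bmi"].mean, INSTRUMENTS["bmi"].sd, n),
                      INSTRUMENTS["bmi"].floor, INSTRUMENTS["bmi"].ceiling)
    findrisc = np.clip(
        np.round(rng.normal(INSTRUMENTS["findrisc"].mean,
                            INSTRUMENTS["findrisc"].sd, n)),
        INSTRUMENTS["findrisc"].floor, INSTRUMENTS["findrisc"].ceiling).astype(int)
    age = np.clip(np.round(rng.normal(config.mean_age, config.sd_age, n)),
                  18, 78).astype(int)
    gender = np.where(rng.random(n) < config.female_proportion,
                      "female", "male")

    subject_ids = [f"s{i:04d}" for i in range(n)]
    agents = []
    for i in range(n):
        params = ParameterSet(alpha=float(alpha[i]),
                              beta_R=float(max(beta_R[i], 1e-6)),
                              beta_E=float(max(beta_E[i], 1e-6)))
        agents.append(task_engine.make_agent(
            subject_ids[i], params,
            capacity_clicks=max(20.0, rng.normal(config.mean_capacity,
                                                 config.sd_capacity)),
            rng=rng))

    covariates = pd.DataFrame({
        "subject_id": subject_ids,
        "shaps": q_scores["shaps"],
        "dars": q_scores["dars"],
        "aes": q_scores["aes"],
        "meq": meq,
        "midsleep_free": _hours_to_clock(midsleep),
        "midsleep_free_hours": np.round(midsleep, 3),
        "bmi": np.round(bmi_raw, 1),
        "findrisc": findrisc,
        "age": age,
        "gender": gender,
        "testing_window": np.where(morning, "morning", "evening"),
        "true_factor": factor,
        "true_chronotype": classes,
        "true_alpha": alpha,
        "true_beta_R": beta_R,
        "true_beta_E": beta_E,
    })
    covariates.attrs["clipped_counts"] = clip_counts
    return agents, covariates


def generate_sessions(agents, model: ModelSpec | str = "full_parabolic",
                      seed=None, session_config=None) -> pd.DataFrame:
    """Simulate one task session per agent; returns the trial-log frame."""
    if isinstance(model, str):
        model = get_model(model)
    rng = np.random.default_rng(seed)
    sessions = [
        task_engine.run_session(a, model, session_config,
                                seed=int(rng.integers(2**31)))
        for a in agents
    ]
    return task_engine.sessions_to_frame(sessions)


def generate_testretest(agents, model: ModelSpec | str = "full_parabolic",
                        seed=None, jitter_alpha: float = 0.25,
                        jitter_log_beta: float = 0.15,
                        session_config=None):
    """Two sessions per agent about a week apart, time-of-day held constant.

    Session-level parameter jitter models state (non-trait) variability:
    additive Normal(0, jitter_alpha) on alpha and multiplicative lognormal
    (sd ``jitter_log_beta`` on the log scale) on the sensitivities, drawn
    independently per session. ``jitter = 0`` reproduces exact parameter
    stability across sessions.

    Returns ``(frame_a, frame_b, truth)`` where ``truth`` records each
    session's effective (jittered) parameters.
    """
    if isinstance(model, str):
        model = get_model(model)
    rng = np.random.default_rng(seed)
    frames, truth_rows = [], []
    for session_tag in ("A", "B"):
        sessions = []
        for a in agents:
            p = a.params
            jittered = ParameterSet(
                alpha=p.alpha + (rng.normal(0, jitter_alpha) if jitter_alpha else 0.0),
                beta_R=p.beta_R * np.exp(rng.normal(0, jitter_log_beta)
                                         if jitter_log_beta else 0.0),
                beta_E=p.beta_E * np.exp(rng.normal(0, jitter_log_beta)
                                         if jitter_log_beta else 0.0))
            sessions.append(task_engine.run_session(
                replace(a, params=jittered), model, session_config,
                seed=int(rng.integers(2**31))))
            truth_rows.append((a.subject_id, session_tag, jittered.alpha,
                               jittered.beta_R, jittered.beta_E))
        frames.append(task_engine.sessions_to_frame(sessions))
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "session", "alpha",
                                              "beta_R", "beta_E"])
    return frames[0], frames[1], truth
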