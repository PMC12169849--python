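"""Model-agnostic task statistics, exclusions, covariate linkage, reliability.

This layer hosts everything downstream of model fitting: compliance-based
exclusion rules, acceptance-proportion summaries and effort x reward F
tests, min-max standardization and directionality handling of the
questionnaires, PLS regression with permutation testing, Bayesian GLMs
(conjugate Gibbs sampling) with an HDI-width stopping rule, chronotype
phenotyping, and test-retest reliability of model parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .model_space import ModelSpec, ParameterSet, get_model, session_loglik

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "acceptance_matrix",
    "EffortRewardTest",
    "effort_reward_test",
    "minmax_standardize",
    "standardized_questionnaires",
    "PLSResult",
    "pls_link",
    "GLMResult",
    "bayesian_glm",
    "classify_chronotype",
    "stopping_rule_met",
    "ReliabilityResult",
    "test_retest",
    "match_controls",
]


# ---------------------------------------------------------------- exclusions

@dataclass
class ExclusionReport:
    """Per-rule exclusion counts plus surviving/flagged subject ids."""

    rules: pd.DataFrame  # rule_id, n_excluded, excluded_ids
    surviving: list
    flagged_missing: list = field(default_factory=list)

    def n_excluded(self, rule_id: str) -> int:
        row = self.rules.set_index("rule_id")
        return int(row.loc[rule_id, "n_excluded"])


def _robust_upper_threshold(values: np.ndarray, n_sd: float = 3.0) -> float:
    """median + n_sd * (MAD-consistent sigma); robust so that re-applying the
    rule to survivors is stable."""
    med = float(np.median(values))
    mad = float(stats.median_abs_deviation(values, scale="normal"))
    if mad == 0:
        mad = float(np.std(values)) or 1e-12
    return med + n_sd * mad


def apply_exclusions(trials: pd.DataFrame, covariates: pd.DataFrame,
                     calibration: pd.DataFrame,
                     min_capacity: float = 7.0,
                     spread_sd: float = 3.0) -> ExclusionReport:
    """Apply the pre-registered compliance rules, in order.

    1. self-reported severe neurological condition / insufficient English
       (columns ``neurological_condition`` / ``english_below_b2``, if present);
    2. catch questions: failing >= 1 easy or both hard questions
       (columns ``easy_catch_failed`` / ``hard_catch_failed``, if present);
    3. rejecting every offer;
    4. clicking calibration capacity below ``min_capacity`` (7 clicks);
    5. within-calibration spread (max - min repetition) beyond
       ``spread_sd`` SDs of the cohort (robust scale estimate);
    6. pre-to-post capacity change beyond ``spread_sd`` SDs of the cohort.

    Subjects missing calibration rows are flagged, not crashed on, and do
    not survive. ``calibration`` needs columns ``subject_id``, ``rep1``,
    ``rep2``, ``rep3`` and optionally ``post_task_clicks``.
    """
    all_ids = list(covariates["subject_id"])
    calib = calibration.set_index("subject_id")
    flagged = [s for s in all_ids if s not in calib.index]
    remaining = [s for s in all_ids if s not in flagged]
    cov = covariates.set_index("subject_id")
    rows = []

    def apply_rule(rule_id, excluded_ids):
        nonlocal remaining
        excluded = [s for s in remaining if s in set(excluded_ids)]
        remaining = [s for s in remaining if s not in set(excluded)]
        rows.append({"rule_id": rule_id, "n_excluded": len(excluded),
                     "excluded_ids": excluded})

    for rule_id, col in (("neurological_condition", "neurological_condition"),
                         ("language", "english_below_b2")):
        if col in cov.columns:
            bad = cov.index[cov[col].astype(bool)]
        else:
            bad = []
        apply_rule(rule_id, bad)

    if {"easy_catch_failed", "hard_catch_failed"} <= set(cov.columns):
        bad = cov.index[(cov["easy_catch_failed"] >= 1)
                        | (cov["hard_catch_failed"] >= 2)]
    else:
        bad = []
    apply_rule("catch_questions", bad)

    accepted = (trials[trials["decision"].isin(["accept", "reject"])]
                .assign(acc=lambda d: d["decision"] == "accept")
                .groupby("subject_id")["acc"].mean())
    apply_rule("all_reject", accepted.index[accepted == 0.0])

    caps = (calib["rep2"] + calib["rep3"]) / 2.0
    apply_rule("calibration_minimum",
               caps.index[caps < min_capacity])

    reps = calib[["rep1", "rep2", "rep3"]].to_numpy(dtype=float)
    spread = pd.Series(reps.max(axis=1) - reps.min(axis=1), index=calib.index)
    spread_cohort = spread.loc[[s for s in remaining if s in spread.index]]
    thr = _robust_upper_threshold(spread_cohort.to_numpy(), spread_sd)
    apply_rule("calibration_spread", spread.index[spread > thr])

    if "post_task_clicks" in calib.columns and calib["post_task_clicks"].notna().any():
        change = (caps - calib["post_task_clicks"]).abs()
        change_cohort = change.loc[[s for s in remaining if s in change.index]]
        thr = _robust_upper_threshold(change_cohort.dropna().to_numpy(), spread_sd)
        apply_rule("pre_post_change", change.index[change > thr])
    else:
        apply_rule("pre_post_change", [])

    return ExclusionReport(rules=pd.DataFrame(rows), surviving=remaining,
                           flagged_missing=flagged)


# ------------------------------------------------------- acceptance summary

def acceptance_matrix(trials: pd.DataFrame):
    """4x4 acceptance proportions (effort level rows, reward columns).

    Cells never offered are NaN, not zero. Returns ``(matrix, overall)``.
    """
    d = trials[trials["decision"].isin(["accept", "reject"])]
    if d.empty:
        raise ValueError("no decided trials")
    acc = d.assign(acc=(d["decision"] == "accept").astype(float))
    matrix = (acc.pivot_table(index="effort_level", columns="reward",
                              values="acc", aggfunc="mean")
              .reindex(index=range(1, 5), columns=range(2, 6)))
    return matrix, float(acc["acc"].mean())


@dataclass
class EffortRewardTest:
    """F tests on subject x cell acceptance proportions."""

    effects: pd.DataFrame  # term, F, df1, df2, p
    posthoc: pd.DataFrame
    cell_data: pd.DataFrame

    def p(self, term: str) -> float:
        return float(self.effects.set_index("term").loc[term, "p"])

    def F(self, term: str) -> float:
        return float(self.effects.set_index("term").loc[term, "F"])


def _f_tests_numeric(cells: pd.DataFrame) -> pd.DataFrame:
    """Single-df F tests of numeric effort, reward and their product on the
    per-subject per-cell acceptance proportion.

    Cells are weighted by their trial counts (the staircases make the cell
    coverage very unbalanced, and corner cells accumulate visits) and the
    numeric predictors are mean-centred so the main effects are average
    slopes rather than slopes extrapolated to level zero."""
    import statsmodels.formula.api as smf

    d = cells.copy()
    d["effort_c"] = d["effort"] - d["effort"].mean()
    d["reward_c"] = d["reward"] - d["reward"].mean()
    fit = smf.wls("acc ~ effort_c + reward_c + effort_c:reward_c", data=d,
                  weights=d["n_trials"]).fit()
    rows = []
    for term, label in (("effort_c", "effort"), ("reward_c", "reward"),
                        ("effort_c:reward_c", "effort:reward")):
        t = fit.tvalues[term]
        rows.append({"term": label, "F": float(t**2), "df1": 1,
                     "df2": int(fit.df_resid), "p": float(fit.pvalues[term])})
    return pd.DataFrame(rows)


def effort_reward_test(trials: pd.DataFrame) -> EffortRewardTest:
    """Main and interaction effects of effort and reward on acceptance.

    The unit of analysis is the subject x offer-cell acceptance proportion
    with numeric effort and reward predictors; post-hoc tests repeat the
    one-predictor test within each level of the other factor.
    """
    d = trials[trials["decision"].isin(["accept", "reject"])]
    if d["subject_id"].nunique() < 2:
        raise ValueError("effort/reward tests require at least 2 subjects")
    cells = (d.assign(acc=(d["decision"] == "accept").astype(float))
             .groupby(["subject_id", "effort_level", "reward"], as_index=False)
             .agg(acc=("acc", "mean"), n_trials=("acc", "size"))
             .rename(columns={"effort_level": "effort"}))
    effects = _f_tests_numeric(cells)

    import statsmodels.formula.api as smf

    post_rows = []
    for level in sorted(cells["reward"].unique()):
        sub = cells[cells["reward"] == level]
        if sub["effort"].nunique() > 1:
            f = smf.wls("acc ~ effort", data=sub, weights=sub["n_trials"]).fit()
            post_rows.append({"within": "reward", "level": int(level),
                              "term": "effort", "F": float(f.tvalues["effort"]**2),
                              "p": float(f.pvalues["effort"])})
    for level in sorted(cells["effort"].unique()):
        sub = cells[cells["effort"] == level]
        if sub["reward"].nunique() > 1:
            f = smf.wls("acc ~ reward", data=sub, weights=sub["n_trials"]).fit()
            post_rows.append({"within": "effort", "level": int(level),
                              "term": "reward", "F": float(f.tvalues["reward"]**2),
                              "p": float(f.pvalues["reward"])})
    return EffortRewardTest(effects=effects, posthoc=pd.DataFrame(post_rows),
                            cell_data=cells)


# ------------------------------------------------------------ standardization

def minmax_standardize(values) -> np.ndarray:
    """Map values linearly onto [0, 1]; rejects constant input."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("cannot min-max standardize a constant vector")
    return (x - lo) / (hi - lo)


#: questionnaires whose native direction is flipped before standardization so
#: that higher always means more severe (psychiatric) or later (circadian)
_FLIPPED = ("dars", "aes", "meq")

QUESTIONNAIRE_PREDICTORS = ("shaps", "dars", "aes", "meq", "mctq", "bmi",
                            "findrisc")


def standardized_questionnaires(covariates: pd.DataFrame) -> pd.DataFrame:
    """The 7-predictor questionnaire matrix on the common [0, 1] scale.

    DARS, AES and MEQ are direction-flipped first (higher = more severe /
    later chronotype); the MCTQ predictor is the free-day mid-sleep time in
    hours (``midsleep_free_hours``).
    """
    out = {}
    for name in QUESTIONNAIRE_PREDICTORS:
        col = "midsleep_free_hours" if name == "mctq" else name
        x = covariates[col].to_numpy(dtype=float)
        if name in _FLIPPED:
            x = -x
        out[name] = minmax_standardize(x)
    return pd.DataFrame(out, index=covariates.index)


# ------------------------------------------------------------------- PLS

@dataclass
class PLSResult:
    n_components: int
    loadings: pd.DataFrame  # predictor weights of retained components
    train_ids: np.ndarray
    test_ids: np.ndarray
    test_rmse: float
    permutation_p: float
    cv_table: pd.DataFrame  # candidate n_components vs CV RMSE


def _cv_rmse(X, y, ncomp, cv_splits, seed):
    kf = KFold(n_splits=cv_splits, shuffle=True, random_state=seed)
    errs = []
    for tr, te in kf.split(X):
        if ncomp == 0:
            pred = np.full(te.size, y[tr].mean())
        else:
            pls = PLSRegression(n_components=ncomp, scale=True)
            pls.fit(X[tr], y[tr])
            pred = pls.predict(X[te]).ravel()
        errs.append(np.mean((y[te] - pred) ** 2))
    return float(np.sqrt(np.mean(errs)))


def pls_link(X: pd.DataFrame, y, *, test_size: float = 0.25,
             cv_splits: int = 10, max_components: int = 4,
             n_permutations: int = 1000, seed=None) -> PLSResult:
    """PLS regression of one model parameter on the questionnaire matrix.

    The data are split 75/25 into training and held-out testing subsets;
    the number of components (0 = intercept-only, which may win) is chosen
    by 10-fold cross-validated RMSE on the training subset; out-of-sample
    RMSE is evaluated on the held-out subset, and its significance by a
    permutation test (proportion of label-permuted test RMSEs at least as
    small, with the +1 correction). Component 1 is oriented so that its
    y-loading is positive, so predictor weights carry the sign of their
    association with the outcome.
    """
    X = pd.DataFrame(X)
    if (X.nunique() <= 1).any():
        bad = list(X.columns[X.nunique() <= 1])
        raise ValueError(f"constant predictor column(s): {bad}")
    y = np.asarray(y, dtype=float)
    if y.size < 40:
        raise ValueError(f"PLS linkage requires n >= 40, got {y.size}")
    rng = np.random.default_rng(seed)
    n = y.size
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_size * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    Xm = X.to_numpy(dtype=float)

    cv_rows = []
    for ncomp in range(0, min(max_components, Xm.shape[1]) + 1):
        cv_rows.append({"n_components": ncomp,
                        "cv_rmse": _cv_rmse(Xm[train_idx], y[train_idx], ncomp,
                                            cv_splits, int(rng.integers(2**31)))})
    cv_table = pd.DataFrame(cv_rows)
    ncomp = int(cv_table.loc[cv_table["cv_rmse"].idxmin(), "n_components"])

    def fit_and_test(y_vec):
        if ncomp == 0:
            pred = np.full(test_idx.size, y_vec[train_idx].mean())
            return None, float(np.sqrt(np.mean((y_vec[test_idx] - pred) ** 2)))
        pls = PLSRegression(n_components=ncomp, scale=True)
        pls.fit(Xm[train_idx], y_vec[train_idx])
        pred = pls.predict(Xm[test_idx]).ravel()
        return pls, float(np.sqrt(np.mean((y_vec[test_idx] - pred) ** 2)))

    pls, test_rmse = fit_and_test(y)
    if pls is None:
        loadings = pd.DataFrame(np.zeros((Xm.shape[1], 0)), index=X.columns)
    else:
        w = pls.x_weights_.copy()
        signs = np.sign(pls.y_loadings_.ravel()[: w.shape[1]])
        signs[signs == 0] = 1.0
        w = w * signs
        loadings = pd.DataFrame(
            w, index=X.columns,
            columns=[f"component_{k + 1}" for k in range(w.shape[1])])

    worse = 0
    for _ in range(n_permutations):
        y_perm = y[rng.permutation(n)]
        _, rmse_perm = fit_and_test(y_perm)
        if rmse_perm <= test_rmse:
            worse += 1
    p = (worse + 1) / (n_permutations + 1)

    return PLSResult(n_components=ncomp, loadings=loadings,
                     train_ids=train_idx, test_ids=test_idx,
                     test_rmse=test_rmse, permutation_p=float(p),
                     cv_table=cv_table)


# ------------------------------------------------------------ Bayesian GLM

@dataclass
class GLMResult:
    """Posterior summaries of a Gaussian GLM (Gibbs-sampled)."""

    coefficients: pd.DataFrame  # name, mean, hdi_low, hdi_high, credible
    covariate_names: list
    draws: Optional[np.ndarray] = None
    coef_names: Optional[list] = None

    def coefficient(self, name: str) -> pd.Series:
        return self.coefficients.set_index("name").loc[name]

    def hdi_width(self, name: str) -> float:
        c = self.coefficient(name)
        return float(c["hdi_high"] - c["hdi_low"])


def bayesian_glm(y, predictors: pd.DataFrame,
                 covariates: Optional[pd.DataFrame] = None,
                 *, prior_sd: float = 1.0, n_draws: int = 4000,
                 n_burn: int = 500, seed=None, hdi_prob: float = 0.95,
                 keep_draws: bool = False) -> GLMResult:
    """Bayesian Gaussian linear model via conjugate Gibbs sampling.

    Coefficients have independent Normal(0, prior_sd^2) priors (the
    intercept a diffuse Normal(0, 10^2)); the noise variance a vague
    inverse-gamma prior. ``covariates`` (typically age and gender) are
    mean-centred and appended to the design; gender is encoded 0/1. A
    coefficient is flagged credible when its HDI excludes zero.
    """
    y = np.asarray(y, dtype=float)
    predictors = pd.DataFrame(predictors)
    parts = [predictors]
    cov_names: list = []
    if covariates is not None and len(covariates.columns):
        cov = covariates.copy()
        for c in cov.columns:
            if cov[c].dtype == object or str(cov[c].dtype) == "category":
                vals = pd.factorize(cov[c], sort=True)[0].astype(float)
                cov[c] = vals
            cov[c] = cov[c].astype(float) - cov[c].astype(float).mean()
        parts.append(cov)
        cov_names = list(cov.columns)
    Xd = pd.concat(parts, axis=1)
    names = ["intercept"] + list(Xd.columns)
    X = np.column_stack([np.ones(y.size), Xd.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    rng = np.random.default_rng(seed)
    p = X.shape[1]
    prior_prec = np.full(p, 1.0 / prior_sd**2)
    prior_prec[0] = 1.0 / 100.0
    XtX, Xty = X.T @ X, X.T @ y
    a0, b0 = 1e-3, 1e-3
    sigma2 = float(np.var(y)) or 1.0
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    draws = np.empty((n_draws, p))
    for it in range(n_burn + n_draws):
        prec = XtX / sigma2 + np.diag(prior_prec)
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xty / sigma2)
        beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
        resid = y - X @ beta
        sigma2 = 1.0 / rng.gamma(a0 + y.size / 2.0,
                                 1.0 / (b0 + 0.5 * float(resid @ resid)))
        if it >= n_burn:
            draws[it - n_burn] = beta

    rows = []
    for j, name in enumerate(names):
        hdi = np.ravel(az.hdi(draws[:, j], hdi_prob=hdi_prob))
        lo, hi = float(hdi[0]), float(hdi[1])
        rows.append({"name": name, "mean": float(draws[:, j].mean()),
                     "hdi_low": lo, "hdi_high": hi,
                     "credible": bool(lo > 0 or hi < 0)})
    return GLMResult(coefficients=pd.DataFrame(rows), covariate_names=cov_names,
                     draws=draws if keep_draws else None, coef_names=names)


# ------------------------------------------------------------- chronotype

def _parse_clock(value) -> float:
    if isinstance(value, str):
        hh, mm = value.split(":")
        v = int(hh) + int(mm) / 60.0
    else:
        v = float(value)
    if not 0 <= v < 24:
        raise ValueError(f"mid-sleep {value!r} is not a valid clock time")
    return v


def classify_chronotype(meq_sum, midsleep_free) -> str:
    """Early / late / intermediate chronotype from MEQ and free-day mid-sleep.

    Early: MEQ sum > 58 and mid-sleep before 02:30; late: MEQ sum < 42 and
    mid-sleep after 05:30; everything else intermediate. ``midsleep_free``
    accepts "HH:MM" strings or decimal hours.
    """
    meq = float(meq_sum)
    if not 16 <= meq <= 86:
        raise ValueError(f"MEQ sum {meq} outside the instrument range 16-86")
    ms = _parse_clock(midsleep_free)
    if meq > 58 and ms < 2.5:
        return "early"
    if meq < 42 and ms > 5.5:
        return "late"
    return "intermediate"


def stopping_rule_met(glm: GLMResult, width_target: float = 0.20,
                      monitor: Optional[Sequence[str]] = None) -> bool:
    """Precision-based stopping: every monitored 95% HDI width <= target.

    By default all coefficients except the intercept and the adjustment
    covariates are monitored; an empty monitor set is an error, never a
    vacuous pass. The boundary (width exactly equal to the target) counts
    as met.
    """
    if monitor is None:
        skip = {"intercept"} | set(glm.covariate_names)
        monitor = [n for n in glm.coefficients["name"] if n not in skip]
    monitor = list(monitor)
    if not monitor:
        raise ValueError("no coefficients to monitor for the stopping rule")
    return all(glm.hdi_width(name) <= width_target for name in monitor)


# ------------------------------------------------------------- reliability

@dataclass
class ReliabilityResult:
    icc: pd.DataFrame  # param, icc, p
    prediction: Optional[pd.DataFrame]
    tests: dict

    def icc_value(self, param: str) -> float:
        return float(self.icc.set_index("param").loc[param, "icc"])


_PARAMS = ("alpha", "beta_R", "beta_E")


def _icc31(a: np.ndarray, b: np.ndarray):
    """ICC(3,1): two-way mixed effects, consistency, single measure."""
    n = a.size
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "session": np.repeat(["A", "B"], n),
        "score": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=long, targets="subject",
                                   raters="session", ratings="score")
    table = table.set_index("Type")
    key = "ICC(C,1)" if "ICC(C,1)" in table.index else "ICC3"
    row = table.loc[key]
    return float(row["ICC"]), float(row["pval"])


def _score_sessions(trials: pd.DataFrame, params_wide: pd.DataFrame,
                    model: ModelSpec) -> pd.DataFrame:
    rows = []
    for sid, sub in trials.groupby("subject_id"):
        p = params_wide.loc[sid]
        pset = ParameterSet(alpha=float(p["alpha"]), beta_R=float(p["beta_R"]),
                            beta_E=float(p["beta_E"]))
        recs = sub.to_dict("records")
        ll = session_loglik(recs, pset, model)
        from .model_space import acceptance_probability, subjective_value, \
            StandardizedOffer
        correct = 0
        for t in recs:
            offer = StandardizedOffer.from_levels(t["effort_level"], t["reward"])
            pr = acceptance_probability(
                subjective_value(offer, model.constrain(pset), model.cost),
                model.constrain(pset).alpha)
            predicted = "accept" if pr > 0.5 else "reject"
            correct += predicted == t["decision"]
        rows.append({"subject_id": sid, "loglik": ll,
                     "accuracy": correct / len(recs), "n_trials": len(recs)})
    return pd.DataFrame(rows).set_index("subject_id")


def test_retest(params_a: pd.DataFrame, params_b: pd.DataFrame,
                sessions_a: Optional[pd.DataFrame] = None,
                sessions_b: Optional[pd.DataFrame] = None,
                group_params: Optional[dict] = None,
                model: ModelSpec | str = "full_parabolic") -> ReliabilityResult:
    """Test-retest reliability of per-subject parameter estimates.

    ``params_a``/``params_b`` are wide frames (index subject_id, columns
    alpha/beta_R/beta_E) of the two sessions' posterior means. ICC(3,1)
    (two-way mixed, consistency, single measure) is reported per
    parameter. When the paired trial logs are supplied, session-A
    parameters additionally predict session-B choices (summed Bernoulli
    log-likelihood and proportion of correctly predicted decisions),
    compared by paired t tests against chance (p = 0.5 per trial) and
    against prediction from group-mean parameters.
    """
    if isinstance(model, str):
        model = get_model(model)
    if set(params_a.index) != set(params_b.index):
        raise ValueError("sessions must contain the same paired subjects")
    params_b = params_b.reindex(params_a.index)

    icc_rows = []
    for param in _PARAMS:
        if param in params_a.columns and params_a[param].nunique() > 1:
            icc, pval = _icc31(params_a[param].to_numpy(dtype=float),
                               params_b[param].to_numpy(dtype=float))
            icc_rows.append({"param": param, "icc": icc, "p": pval})
    icc_df = pd.DataFrame(icc_rows)

    prediction, tests = None, {}
    if sessions_b is not None:
        scored = _score_sessions(sessions_b, params_a, model)
        if group_params is None:
            group_params = {p: float(params_a[p].mean()) for p in _PARAMS
                            if p in params_a.columns}
        group_wide = pd.DataFrame(
            {p: group_params.get(p, 1.0 if p != "alpha" else 0.0)
             for p in _PARAMS}, index=params_a.index)
        scored_group = _score_sessions(sessions_b, group_wide, model)
        chance_ll = scored["n_trials"] * np.log(0.5)
        prediction = pd.DataFrame({
            "loglik_ownparams": scored["loglik"],
            "loglik_groupparams": scored_group["loglik"],
            "loglik_chance": chance_ll,
            "accuracy_ownparams": scored["accuracy"],
            "accuracy_groupparams": scored_group["accuracy"],
        })
        t1 = stats.ttest_rel(scored["loglik"], chance_ll, alternative="greater")
        t2 = stats.ttest_rel(scored["loglik"], scored_group["loglik"],
                             alternative="greater")
        tests = {
            "vs_chance": {"t": float(t1.statistic), "p": float(t1.pvalue)},
            "vs_group": {"t": float(t2.statistic), "p": float(t2.pvalue)},
        }
    return ReliabilityResult(icc=icc_df, prediction=prediction, tests=tests)


# ---------------------------------------------------------------- utilities

def match_controls(cases: pd.DataFrame, pool: pd.DataFrame,
                   age_col: str = "age", gender_col: str = "gender") -> list:
    """Nearest-age, exact-gender control matching (greedy, without
    replacement). Returns the matched control subject ids."""
    available = pool.copy()
    matched = []
    for _, case in cases.iterrows():
        candidates = available[available[gender_col] == case[gender_col]]
        if candidates.empty:
            continue
        idx = (candidates[age_col] - case[age_col]).abs().idxmin()
        matched.append(available.loc[idx, "subject_id"])
        available = available.drop(index=idx)
    return matched
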