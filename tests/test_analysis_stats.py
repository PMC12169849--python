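import numpy as np
import pandas as pd
import pytest

from effortdm import analysis_stats as st
from effortdm import synthetic_data as sd
from conftest import make_cohort


def _toy_cohort(n=10, all_reject_idx=None, low_capacity_idx=None,
                catch_fail_idx=None, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i:02d}" for i in range(n)]
    trials = []
    for i, s in enumerate(ids):
        for t in range(8):
            reject = (all_reject_idx == i)
            trials.append({"subject_id": s, "trial": t + 1, "block": 1,
                           "staircase": t + 1, "effort_level": 1 + t % 4,
                           "reward": 2 + t % 4,
                           "decision": "reject" if reject else
                           ("accept" if rng.random() < 0.7 else "reject"),
                           "success": True, "clicks": 50, "points": 3})
    cov = pd.DataFrame({
        "subject_id": ids,
        "easy_catch_failed": [1 if catch_fail_idx == i else 0
                              for i in range(n)],
        "hard_catch_failed": 0,
    })
    calib = pd.DataFrame({
        "subject_id": ids,
        "rep1": 55, "rep2": 60, "rep3": 62,
        "post_task_clicks": 59,
    })
    if low_capacity_idx is not None:
        calib.loc[low_capacity_idx, ["rep2", "rep3"]] = 6
    return pd.DataFrame(trials), cov, calib


class TestExclusions:
    def test_all_reject_subject_excluded(self):
        trials, cov, calib = _toy_cohort(all_reject_idx=3)
        rep = st.apply_exclusions(trials, cov, calib)
        assert rep.n_excluded("all_reject") == 1
        assert "p03" not in rep.surviving
        assert len(rep.surviving) == 9

    def test_low_capacity_excluded_at_threshold_seven(self):
        trials, cov, calib = _toy_cohort(low_capacity_idx=2)
        rep = st.apply_exclusions(trials, cov, calib)
        assert rep.n_excluded("calibration_minimum") == 1
        assert "p02" not in rep.surviving

    def test_one_easy_catch_failure_excluded(self):
        trials, cov, calib = _toy_cohort(catch_fail_idx=5)
        rep = st.apply_exclusions(trials, cov, calib)
        assert rep.n_excluded("catch_questions") == 1

    def test_missing_calibration_flagged_not_crashed(self):
        trials, cov, calib = _toy_cohort()
        rep = st.apply_exclusions(trials, cov, calib.iloc[1:])
        assert rep.flagged_missing == ["p00"]
        assert "p00" not in rep.surviving

    def test_idempotent_on_survivors(self):
        trials, cov, calib = _toy_cohort(all_reject_idx=1, low_capacity_idx=4)
        rep = st.apply_exclusions(trials, cov, calib)
        kept = set(rep.surviving)
        rep2 = st.apply_exclusions(
            trials[trials["subject_id"].isin(kept)],
            cov[cov["subject_id"].isin(kept)],
            calib[calib["subject_id"].isin(kept)])
        assert set(rep2.surviving) == kept
        assert rep2.rules["n_excluded"].sum() == 0

    def test_counts_sum_consistently(self):
        trials, cov, calib = _toy_cohort(all_reject_idx=0, catch_fail_idx=7)
        rep = st.apply_exclusions(trials, cov, calib)
        assert (rep.rules["n_excluded"].sum() + len(rep.surviving)
                + len(rep.flagged_missing)) == len(cov)


class TestAcceptanceMatrix:
    def test_all_accept(self):
        trials, _, _ = _toy_cohort(n=2, seed=1)
        trials["decision"] = "accept"
        m, overall = st.acceptance_matrix(trials)
        assert overall == 1.0
        assert np.nanmax(m.values) == np.nanmin(m.values) == 1.0

    def test_hand_counted_alternating_fixture(self):
        rows = []
        for i, (e, r) in enumerate([(1, 2), (1, 2), (3, 4), (3, 4)]):
            rows.append({"subject_id": "a", "trial": i + 1, "block": 1,
                         "staircase": 1, "effort_level": e, "reward": r,
                         "decision": "accept" if i % 2 == 0 else "reject",
                         "success": True, "clicks": 1, "points": 1})
        m, overall = st.acceptance_matrix(pd.DataFrame(rows))
        assert m.loc[1, 2] == 0.5 and m.loc[3, 4] == 0.5
        assert overall == 0.5

    def test_unoffered_cells_missing_not_zero(self):
        rows = [{"subject_id": "a", "trial": 1, "block": 1, "staircase": 1,
                 "effort_level": 1, "reward": 2, "decision": "accept",
                 "success": True, "clicks": 1, "points": 2}]
        m, _ = st.acceptance_matrix(pd.DataFrame(rows))
        assert m.loc[1, 2] == 1.0
        assert m.drop(index=1).isna().all().all()


class TestEffortRewardTest:
    def test_strong_discounting_yields_significant_main_effects(self):
        df = make_cohort(60, seed=21, alpha=1.0, sd_alpha=0.3, beta_R=2.5,
                         beta_E=2.5)
        res = st.effort_reward_test(df)
        assert res.p("effort") < 1e-3
        assert res.p("reward") < 1e-3
        assert res.effects.set_index("term").loc["effort", "df1"] == 1
        # post-hoc: effort effect at every reward level
        post = res.posthoc
        assert (post[post["term"] == "effort"]["p"] < 0.05).all()

    def test_requires_two_subjects(self):
        df = make_cohort(1, seed=2)
        with pytest.raises(ValueError):
            st.effort_reward_test(df)


class TestMinMax:
    def test_basic_examples(self):
        assert np.allclose(st.minmax_standardize([2, 4, 6]), [0, 0.5, 1])
        x = np.array([0.0, 0.3, 1.0])
        assert np.allclose(st.minmax_standardize(x), x)

    def test_range_contract(self, rng):
        x = rng.normal(size=50)
        out = st.minmax_standardize(x)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            st.minmax_standardize([3, 3, 3])


@pytest.fixture(scope="module")
def paper_like_cov():
    _, cov = sd.generate_population(
        sd.paper_like_config(n_subjects=400, seed=31))
    return cov


class TestPLS:
    def test_loading_pattern_for_acceptance_bias(self, paper_like_cov):
        """The symptom questionnaires should dominate component 1 with
        negative sign when predicting the acceptance bias."""
        X = st.standardized_questionnaires(paper_like_cov)
        y = st.minmax_standardize(paper_like_cov["true_alpha"])
        res = st.pls_link(X, y, n_permutations=50, seed=3)
        assert res.n_components >= 1
        w = res.loadings["component_1"]
        symptom = w[["shaps", "dars", "aes"]]
        other = w[["bmi", "findrisc"]]
        assert (symptom < 0).all()
        assert symptom.abs().min() > other.abs().max()

    def test_constant_column_flagged(self, paper_like_cov):
        X = st.standardized_questionnaires(paper_like_cov).copy()
        X["bmi"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            st.pls_link(X, np.arange(len(X), dtype=float), seed=0)

    def test_small_sample_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 7)))
        with pytest.raises(ValueError):
            st.pls_link(X, np.arange(20.0), seed=0)

    def test_permutation_p_floored(self, paper_like_cov):
        X = st.standardized_questionnaires(paper_like_cov)
        y = st.minmax_standardize(paper_like_cov["true_alpha"])
        res = st.pls_link(X, y, n_permutations=19, seed=4)
        assert res.permutation_p >= 1 / 20


class TestBayesianGLM:
    def test_known_slope_recovered(self, rng):
        x = rng.uniform(0, 1, 500)
        y = 0.5 - 0.2 * x + rng.normal(0, 0.05, 500)
        glm = st.bayesian_glm(y, pd.DataFrame({"x": x}), seed=0)
        coef = glm.coefficient("x")
        assert -0.25 < coef["mean"] < -0.15
        assert coef["credible"]

    def test_null_slope_interval_contains_zero(self, rng):
        contains = 0
        for rep in range(20):
            x = rng.uniform(0, 1, 200)
            y = 0.5 + rng.normal(0, 0.05, 200)
            glm = st.bayesian_glm(y, pd.DataFrame({"x": x}), seed=rep,
                                  n_draws=1500, n_burn=300)
            contains += not glm.coefficient("x")["credible"]
        assert contains >= 17  # ~95% coverage

    def test_rank_deficient_design_flagged(self):
        x = np.ones(50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            st.bayesian_glm(np.zeros(50), X)

    def test_covariates_adjusted_and_gender_encoded(self, rng):
        n = 300
        age = rng.integers(20, 70, n)
        gender = rng.choice(["female", "male"], n)
        x = rng.uniform(0, 1, n)
        y = 0.3 - 0.2 * x + 0.002 * age + rng.normal(0, 0.05, n)
        glm = st.bayesian_glm(y, pd.DataFrame({"x": x}),
                              pd.DataFrame({"age": age, "gender": gender}),
                              seed=1)
        assert set(glm.covariate_names) == {"age", "gender"}
        assert -0.25 < glm.coefficient("x")["mean"] < -0.15

    def test_circadian_preset_sign_pattern(self):
        """On generated truths, the late-chronotype main effect on the
        standardized acceptance bias is credibly negative and the
        chronotype-by-evening interaction credibly positive."""
        _, cov = sd.generate_population(
            sd.paper_like_config(n_subjects=2500, seed=33))
        sub = cov[cov["true_chronotype"].isin(["early", "late"])].copy()
        sub["late"] = (sub["true_chronotype"] == "late").astype(float)
        sub["evening"] = (sub["testing_window"] == "evening").astype(float)
        sub["late_x_evening"] = sub["late"] * sub["evening"]
        y = st.minmax_standardize(sub["true_alpha"])
        glm = st.bayesian_glm(
            y, sub[["late", "evening", "late_x_evening"]],
            sub[["age", "gender"]], seed=2)
        late = glm.coefficient("late")
        inter = glm.coefficient("late_x_evening")
        assert late["mean"] < 0 and late["credible"]
        assert inter["mean"] > 0 and inter["credible"]


class TestChronotype:
    @pytest.mark.parametrize("meq, ms_, expected", [
        (60, "02:00", "early"),
        (41, "06:00", "late"),
        (60, "03:00", "intermediate"),  # conjunction fails
        (50, "02:00", "intermediate"),
        (41, 6.5, "late"),              # decimal hours accepted
    ])
    def test_classification_rule(self, meq, ms_, expected):
        assert st.classify_chronotype(meq, ms_) == expected

    def test_out_of_range_meq_rejected(self):
        with pytest.raises(ValueError):
            st.classify_chronotype(10, "03:00")

    def test_invalid_clock_rejected(self):
        with pytest.raises(ValueError):
            st.classify_chronotype(50, 25.0)


def _glm_with_widths(widths):
    rows = [{"name": "intercept", "mean": 0.5, "hdi_low": 0.4,
             "hdi_high": 0.6, "credible": True}]
    for i, w in enumerate(widths):
        rows.append({"name": f"x{i}", "mean": 0.0, "hdi_low": -w / 2,
                     "hdi_high": w / 2, "credible": False})
    return st.GLMResult(coefficients=pd.DataFrame(rows), covariate_names=[])


class TestStoppingRule:
    def test_boundary_width_counts_as_met(self):
        assert st.stopping_rule_met(_glm_with_widths([0.20]))

    def test_wide_interval_fails(self):
        assert not st.stopping_rule_met(_glm_with_widths([0.30, 0.10]))

    def test_empty_monitor_set_is_error(self):
        glm = _glm_with_widths([0.1])
        with pytest.raises(ValueError):
            st.stopping_rule_met(glm, monitor=[])


class TestTestRetest:
    def _params(self, rng, n=30):
        return pd.DataFrame({
            "alpha": rng.normal(1, 1, n),
            "beta_R": rng.lognormal(0.6, 0.4, n),
            "beta_E": rng.lognormal(0.6, 0.4, n),
        }, index=[f"s{i}" for i in range(n)])

    def test_identical_parameters_icc_one(self, rng):
        p = self._params(rng)
        rel = st.test_retest(p, p.copy())
        assert np.allclose(rel.icc["icc"], 1.0)

    def test_independent_parameters_icc_near_zero(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            rel = st.test_retest(self._params(rng), self._params(rng))
            hits += (rel.icc["icc"].abs() < 0.35).all()
        assert hits >= 17

    def test_unpaired_subjects_rejected(self, rng):
        a = self._params(rng)
        b = self._params(rng).iloc[:-1]
        with pytest.raises(ValueError):
            st.test_retest(a, b)


class TestMatchControls:
    def test_nearest_age_exact_gender(self):
        cases = pd.DataFrame({"subject_id": ["c1", "c2"], "age": [30, 60],
                              "gender": ["female", "male"]})
        pool = pd.DataFrame({"subject_id": ["h1", "h2", "h3"],
                             "age": [29, 45, 61],
                             "gender": ["female", "female", "male"]})
        assert st.match_controls(cases, pool) == ["h1", "h3"]
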