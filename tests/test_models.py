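import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import physpref as pp
from physpref import study
from physpref.models import (
    DEFAULT_PREDICTORS,
    DegenerateOutcomeError,
    ModelSpec,
    UnderIdentifiedError,
    hc3_sandwich,
)

import statsmodels.api as sm


class TestBuildDesign:
    def test_column_count_and_order(self, exact_cohort):
        imputed = pp.impute_covariates(exact_cohort)
        X, y, exclusions = pp.build_design(imputed, "consultation")
        # intercept + gender male + 4 age + 2 disease + 7 binary flags
        assert X.shape[1] == 15
        assert list(X.columns[:3]) == ["intercept", "gender[male]", "age_group[<20]"]
        assert exclusions == {"gender_diverse": 1}
        assert X.shape[0] == 323
        assert len(y) == 323

    def test_all_reference_record_is_intercept_only(self, codebook):
        counts = {s: (15, 8) for s in study.SCENARIOS}
        cohort = pp.cohort_from_scenario_counts(counts, n=40)
        data = cohort.data.copy()
        ref_row = {
            v.name: v.reference for v in codebook.covariates
        }
        for k, val in ref_row.items():
            data.loc[0, k] = val
        data.loc[0, "last_physician_gender"] = "female"
        data.loc[0, "advice_better_other_gender"] = "no"
        X, _, _ = pp.build_design(pp.CohortTable(data), "consultation")
        row = X.loc[0].to_numpy()
        assert row[0] == 1.0 and (row[1:] == 0.0).all()

    def test_direction_outcome_excludes_non_preferrers(self, exact_cohort):
        spec = ModelSpec(outcome="direction_female")
        X, y, exclusions = pp.build_design(exact_cohort, "consultation", spec)
        assert exclusions["no_preference"] > 0
        assert len(y) < 324

    def test_unimputed_covariates_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="impute"):
            pp.build_design(small_cohort, "consultation")

    def test_constant_outcome_is_degenerate(self):
        counts = {s: (0, 0) for s in study.SCENARIOS}
        cohort = pp.cohort_from_scenario_counts(counts, n=30)
        with pytest.raises(DegenerateOutcomeError):
            pp.build_design(cohort, "consultation")

    def test_too_few_records_under_identified(self):
        counts = {s: (5, 3) for s in study.SCENARIOS}
        cohort = pp.cohort_from_scenario_counts(counts, n=10)
        with pytest.raises(UnderIdentifiedError):
            pp.build_design(cohort, "consultation")


class TestHC3:
    def _fixture(self):
        # same construction frozen into the R oracle below
        rng = np.random.default_rng(42)
        n = 60
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < expit(-0.3 + 0.8 * x1 - 0.5 * x2)).astype(float)
        X = np.column_stack([np.ones(n), x1, x2])
        return X, y

    def test_matches_r_sandwich_oracle(self):
        """Frozen oracle: R `glm` + `sandwich::vcovHC(type="HC3")` on the
        identical 60-record fixture (computed once, independently)."""
        X, y = self._fixture()
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10)
        se = np.sqrt(np.diag(hc3_sandwich(X, y, np.asarray(res.params))))
        r_coefs = [-0.3531569235, 1.1820517982, -0.7978620341]
        r_se = [0.4234072998, 0.5813230580, 0.6493861824]
        np.testing.assert_allclose(res.params, r_coefs, rtol=1e-6)
        np.testing.assert_allclose(se, r_se, rtol=1e-5)

    def test_hc3_close_to_conventional_at_homogeneous_leverage(self):
        """Balanced design, large n: robust and model-based CIs agree to 5%."""
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        y = (rng.random(n) < expit(-0.2 + 0.5 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        se_hc3 = np.sqrt(np.diag(hc3_sandwich(X, y, np.asarray(res.params))))
        np.testing.assert_allclose(se_hc3, res.bse, rtol=0.05)


class TestAnyPreferenceFit:
    def test_null_fit_ors_within_sampling_bound(self):
        """All ORs near 1 on a null cohort, judged against an analytic
        3-sigma bound per term (2x2 log-OR variance from the generator's
        marginals — sparse dummies legitimately wander further)."""
        cfg = pp.default_config(seed=11)
        cfg.n = 5000
        cfg.missingness_rates = {}
        cohort = pp.generate(cfg)
        res = pp.fit_any_preference(cohort, "consultation")
        assert res.valid_inference
        prev = study.scenario_prevalence("consultation")
        marginals = cfg.covariate_marginals
        for term, row in res.table.drop("intercept").iterrows():
            var, level = term[:-1].split("[")
            p_exp = marginals[var][level]
            var_log_or = (1 / p_exp + 1 / (1 - p_exp)) / (
                cfg.n * prev * (1 - prev)
            )
            bound = np.exp(3 * np.sqrt(var_log_or))
            assert 1 / bound < row["or_"] < bound, term

    def test_result_invariants(self, small_cohort):
        res = pp.fit_any_preference(small_cohort, "operation")
        t = res.table
        assert ((t["ci_low"] < t["or_"]) & (t["or_"] < t["ci_high"])).all()
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()
        assert res.n_obs + res.n_excluded == 324

    def test_invariant_to_predictor_reordering(self, small_cohort):
        res_a = pp.fit_any_preference(small_cohort, "examination")
        spec = ModelSpec(predictors=tuple(reversed(DEFAULT_PREDICTORS)))
        res_b = pp.fit_any_preference(small_cohort, "examination", spec)
        common = res_a.table.index
        pd.testing.assert_frame_equal(
            res_a.table.loc[common], res_b.table.loc[common], rtol=1e-8
        )

    def test_expanded_model_leaves_core_terms_stable(self):
        """Adding education/religion/relationship/GP to a null cohort moves
        core-term ORs by <10% in median."""
        cfg = pp.default_config(seed=21)
        cfg.n = 5000
        cfg.missingness_rates = {}
        cohort = pp.generate(cfg)
        core = pp.fit_any_preference(cohort, "examination")
        expanded = pp.fit_any_preference(
            cohort, "examination", ModelSpec(expanded=True)
        )
        terms = core.table.index.drop("intercept")
        rel_change = np.abs(
            expanded.table.loc[terms, "or_"] / core.table.loc[terms, "or_"] - 1
        )
        assert np.median(rel_change) < 0.10

    def test_conventional_covariance_option(self, small_cohort):
        res = pp.fit_any_preference(
            small_cohort, "operation", ModelSpec(covariance="conventional")
        )
        assert res.valid_inference


class TestDirectionFit:
    def test_planted_direction_effect_recovered(self):
        """A log(2) male-patient effect on female-direction preference is
        recovered at large n."""
        cfg = pp.default_config(seed=31)
        cfg.n = 20_000
        cfg.missingness_rates = {}
        cohort = pp.generate(cfg)
        # rewire direction: male patients prefer female physicians at OR 2
        data = cohort.data.copy()
        rng = np.random.default_rng(99)
        base = 0.45
        p = np.where(
            data["gender"] == "male",
            expit(np.log(base / (1 - base)) + np.log(2.0)),
            base,
        )
        for s in study.SCENARIOS:
            col = study.pref_column(s)
            pref = data[col].isin(["female", "male"]).to_numpy()
            female = rng.random(len(data)) < p
            data.loc[pref, col] = np.where(female[pref], "female", "male")
        res = pp.fit_direction(pp.CohortTable(data), "consultation")
        assert res.table.loc["gender[male]", "or_"] == pytest.approx(2.0, abs=0.2)

    def test_null_direction_type_one_error(self):
        """Direction independent of covariates: no term rejects in more than
        10% of replicates at n=5000."""
        reps = 200
        rej = None
        for i in range(reps):
            cfg = pp.default_config(seed=1000 + i)
            cfg.n = 5000
            cfg.missingness_rates = {}
            cohort = pp.generate(cfg)
            res = pp.fit_direction(cohort, "consultation")
            p = res.table["p"].drop("intercept")
            if rej is None:
                rej = np.zeros(len(p))
            rej += (p.to_numpy() < 0.05).astype(float)
        assert (rej / reps <= 0.10).all()

    def test_unanimous_direction_is_degenerate(self):
        counts = {s: (40, 40) for s in study.SCENARIOS}  # everyone female
        cohort = pp.cohort_from_scenario_counts(counts, n=60)
        with pytest.raises(DegenerateOutcomeError):
            pp.fit_direction(cohort, "consultation")


class TestPower:
    def test_null_calibration(self):
        res = pp.power_sensitivity(or_grid=(1.0,), replicates=2000, seed=4)
        assert res.power[0] == pytest.approx(0.05, abs=3 * max(res.mc_se[0], 1e-3))

    def test_large_effect_near_certain_detection(self):
        res = pp.power_sensitivity(or_grid=(3.0,), replicates=1000, seed=4)
        assert res.power[0] > 0.99

    def test_power_monotone_in_effect_size(self):
        res = pp.power_sensitivity(
            or_grid=(1.0, 1.5, 2.0, 3.0), replicates=1000, seed=4
        )
        assert list(res.power) == sorted(res.power)

    def test_validation(self):
        with pytest.raises(ValueError):
            pp.power_sensitivity(baseline=1.2)
        with pytest.raises(ValueError):
            pp.power_sensitivity(replicates=10)
        with pytest.raises(ValueError):
            pp.power_sensitivity(or_grid=())
        with pytest.raises(ValueError):
            pp.power_sensitivity(alpha=0.0)
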