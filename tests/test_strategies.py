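"""Propensity models, adjustment mechanisms, outcome models, balance."""

import numpy as np
import pandas as pd
import pytest

from fmasurv.strategies import (
    PairwiseData,
    StrategySpec,
    balance_report,
    fit_propensity,
    fit_strategy,
    ipw_ate,
    matched_ate,
    strategy_ate,
    stratified_ate,
)
from fmasurv.synthetic import benchmark_config, generate_cohort, true_estimands
from fmasurv.fma import AnalysisConfig, _prepare_pairwise


def make_data(X, treatment, pseudo, functional="rmst", time=None, event=None, t0=3.2):
    n = len(X)
    return PairwiseData(
        X=X,
        treatment=np.asarray(treatment),
        pseudo=np.asarray(pseudo, dtype=float),
        time=np.ones(n) if time is None else np.asarray(time, dtype=float),
        event=np.ones(n, dtype=int) if event is None else np.asarray(event, dtype=int),
        functional=functional,
        t0=t0,
    )


def benchmark_data(kind="confounded", n_per_arm=1500, seed=0, estimand="rhr"):
    cfg = benchmark_config(kind, n_per_arm=n_per_arm, seed=seed)
    coh = generate_cohort(cfg)
    ac = AnalysisConfig(
        reference_arm="control", comparator_arm="treated", estimand=estimand,
        n_bootstrap=0, seed=seed,
    )
    return _prepare_pairwise(coh, ac)


class TestFitPropensity:
    def test_logistic_score_equation_identity(self, rng):
        # ML logistic scores average to the treated fraction
        n = 2000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.integers(0, 2, n)
        scores = fit_propensity("logistic", X, t).scores(X)
        assert scores.mean() == pytest.approx(t.mean(), abs=1e-8)

    def test_saturated_binary_confounder(self, rng):
        n = 4000
        z = rng.integers(0, 2, n)
        t = (rng.random(n) < np.where(z == 1, 0.8, 0.2)).astype(int)
        X = pd.DataFrame({"z": z})
        scores = fit_propensity("logistic", X, t).scores(X)
        assert scores[z == 1].mean() == pytest.approx(t[z == 1].mean(), abs=1e-6)
        assert scores[z == 0].mean() == pytest.approx(t[z == 0].mean(), abs=1e-6)

    def test_constant_covariates_give_treated_fraction(self, rng):
        n = 200
        X = pd.DataFrame({"c": np.ones(n)})
        t = rng.integers(0, 2, n)
        scores = fit_propensity("logistic", X, t).scores(X)
        np.testing.assert_allclose(scores, t.mean(), atol=1e-8)

    @pytest.mark.parametrize(
        "model", ["logistic_stepwise", "logistic_penalised", "random_forest", "gradient_boosting"]
    )
    def test_all_models_produce_valid_scores(self, model, rng):
        n = 400
        z = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        t = (rng.random(n) < 0.3 + 0.4 * z).astype(int)
        X = pd.DataFrame({"z": z, "x": x})
        scores = fit_propensity(model, X, t, seed=0).scores(X)
        assert np.all((scores > 0) & (scores < 1))
        # the informative covariate should separate the score distribution
        assert scores[z == 1].mean() > scores[z == 0].mean()

    def test_stepwise_ignores_noise_columns(self, rng):
        n = 800
        z = rng.integers(0, 2, n)
        t = (rng.random(n) < 0.25 + 0.5 * z).astype(int)
        X = pd.DataFrame({"z": z, "noise": rng.normal(size=n)})
        scores = fit_propensity("logistic_stepwise", X, t, seed=0).scores(X)
        assert abs(np.corrcoef(scores, z)[0, 1]) > 0.99


class TestIPW:
    def test_constant_scores_reduce_to_unweighted_contrast(self, rng):
        n = 100
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = np.repeat([0, 1], n // 2)
        y = rng.normal(size=n)
        data = make_data(X, t, y)
        fs = ipw_ate(data, np.full(n, 0.5), StrategySpec("ipw", "logistic", "ipw"))
        m0, m1 = fs.counterfactuals(X)
        assert m0[0] == pytest.approx(y[t == 0].mean())
        assert m1[0] == pytest.approx(y[t == 1].mean())

    def test_four_patient_hajek_hand_computation(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        t = np.array([1, 1, 0, 0])
        y = np.array([2.0, 3.0, 1.0, 4.0])
        scores = np.array([0.8, 0.6, 0.4, 0.2])
        data = make_data(X, t, y)
        fs = ipw_ate(data, scores, StrategySpec("ipw", "logistic", "ipw"))
        # hand Hájek: treated weights 1/e, control weights 1/(1-e)
        w1 = np.array([1 / 0.8, 1 / 0.6])
        w0 = np.array([1 / 0.6, 1 / 0.8])
        m0, m1 = fs.counterfactuals(X)
        assert m1[0] == pytest.approx((w1 @ [2, 3]) / w1.sum())
        assert m0[0] == pytest.approx((w0 @ [1, 4]) / w0.sum())

    def test_randomized_large_n_matches_unadjusted(self):
        data = benchmark_data("null", n_per_arm=2000, seed=3)
        scores = fit_propensity("logistic", data.X, data.treatment).scores(data.X)
        fs = ipw_ate(data, scores, StrategySpec("ipw", "logistic", "ipw"))
        unadj = fit_strategy(StrategySpec("u", outcome_model="arm_means"), data)
        assert strategy_ate(fs, data) == pytest.approx(strategy_ate(unadj, data), abs=0.03)

    def test_true_propensity_is_unbiased_over_replicates(self):
        # Hájek IPW with the true scores across seeded replicates
        from scipy.special import expit

        truth = true_estimands(benchmark_config("confounded", n_per_arm=100)).true_rhr
        ests = []
        for s in range(20):
            data = benchmark_data("confounded", n_per_arm=1000, seed=300 + s)
            e_true = expit(1.2 * data.X["comorbidity"].to_numpy())
            fs = ipw_ate(data, e_true, StrategySpec("ipw", "logistic", "ipw"))
            ests.append(strategy_ate(fs, data))
        err = np.mean(np.log(ests)) - np.log(truth)
        se = np.std(np.log(ests), ddof=1) / np.sqrt(len(ests))
        assert abs(err) < 3 * se + 0.01


class TestStratification:
    def test_single_stratum_equals_unadjusted(self, rng):
        data = benchmark_data("confounded", n_per_arm=300, seed=5)
        prop = fit_propensity("logistic", data.X, data.treatment)
        fs = stratified_ate(data, prop, StrategySpec("s", "logistic", "stratification"), n_strata=1)
        unadj = fit_strategy(StrategySpec("u", outcome_model="arm_means"), data)
        assert strategy_ate(fs, data) == pytest.approx(strategy_ate(unadj, data), abs=1e-9)

    def test_constant_scores_equal_unadjusted(self, rng):
        n = 200
        X = pd.DataFrame({"c": np.ones(n)})
        t = np.repeat([0, 1], n // 2)
        y = rng.normal(size=n)
        data = make_data(X, t, y)
        prop = fit_propensity("logistic", X, t)
        fs = stratified_ate(data, prop, StrategySpec("s", "logistic", "stratification"))
        m0, m1 = fs.counterfactuals(X)
        assert np.mean(m1) - np.mean(m0) == pytest.approx(
            y[t == 1].mean() - y[t == 0].mean(), abs=1e-9
        )

    def test_two_strata_hand_computation(self):
        # stratum A: scores ~0.3, stratum B: scores ~0.7, 4 patients each
        X = pd.DataFrame({"g": [0, 0, 0, 0, 1, 1, 1, 1]})
        t = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])

        class FakeProp:
            def scores(self, Xn):
                return np.where(Xn["g"] == 1, 0.7, 0.3)

        data = make_data(X, t, y)
        fs = stratified_ate(data, FakeProp(), StrategySpec("s", "logistic", "stratification"),
                            n_strata=2)
        m0, m1 = fs.counterfactuals(X)
        # equal strata: contrast = mean of within-stratum contrasts = 2.0
        assert np.mean(m1) - np.mean(m0) == pytest.approx(
            0.5 * ((3.5 - 1.5) + (7.5 - 5.5))
        )


class TestMatching:
    def test_duplicated_arms_recover_unadjusted(self, rng):
        n = 60
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": np.concatenate([x, x])})
        t = np.repeat([1, 0], n)
        y = rng.normal(size=2 * n)
        data = make_data(X, t, y)
        scores = fit_propensity("logistic", X, t).scores(X)
        fs = matched_ate(data, scores, StrategySpec("m", "logistic", "matching"), seed=0)
        assert fs.info["n_pairs"] == n
        assert fs.info["n_unmatched_treated"] == 0
        m0, m1 = fs.counterfactuals(X)
        assert np.mean(m1) - np.mean(m0) == pytest.approx(
            y[t == 1].mean() - y[t == 0].mean(), abs=1e-9
        )

    def test_out_of_caliper_treated_left_unmatched(self):
        # controls clustered at score 0.3; one treated far away at 0.9
        scores = np.array([0.30, 0.31, 0.32, 0.33, 0.301, 0.311, 0.90])
        t = np.array([1, 1, 1, 0, 0, 0, 1])
        X = pd.DataFrame({"x": scores})
        y = np.arange(7, dtype=float)
        data = make_data(X, t, y)
        fs = matched_ate(data, scores, StrategySpec("m", "logistic", "matching"), seed=1)
        assert fs.info["n_unmatched_treated"] == 1
        assert fs.info["n_pairs"] == 3

    def test_seeded_determinism(self, rng):
        data = benchmark_data("confounded", n_per_arm=400, seed=8)
        scores = fit_propensity("logistic", data.X, data.treatment).scores(data.X)
        spec = StrategySpec("m", "logistic", "matching")
        a = matched_ate(data, scores, spec, seed=5)
        b = matched_ate(data, scores, spec, seed=5)
        assert strategy_ate(a, data) == strategy_ate(b, data)
        assert a.info == b.info


class TestOutcomeModels:
    def test_null_outcome_model_gives_null_ate(self, rng):
        # outcome independent of treatment and covariates
        n = 400
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = np.repeat([0, 1], n // 2)
        y = np.full(n, 2.5)
        data = make_data(X, t, y)
        fs = fit_strategy(StrategySpec("g", outcome_model="gradient_boosting"), data, seed=0)
        m0, m1 = fs.counterfactuals(X)
        assert np.mean(m1) - np.mean(m0) == pytest.approx(0.0, abs=1e-9)

    def test_correctly_specified_model_recovers_hazard_ratio(self):
        data = benchmark_data("confounded", n_per_arm=4000, seed=17)
        truth = true_estimands(benchmark_config("confounded", n_per_arm=100)).true_rhr
        fs = fit_strategy(StrategySpec("cox", outcome_model="cox_main_effects"), data)
        assert strategy_ate(fs, data) == pytest.approx(truth, abs=0.05)

    def test_per_arm_identical_laws_give_null(self):
        data = benchmark_data("null", n_per_arm=1500, seed=23)
        fs = fit_strategy(
            StrategySpec("w", outcome_model="parametric_survival", per_arm=True), data
        )
        assert strategy_ate(fs, data) == pytest.approx(1.0, abs=0.08)

    @pytest.mark.parametrize(
        "om", ["cox_two_way", "penalised_cox", "parametric_survival", "random_forest"]
    )
    def test_outcome_models_finite_predictions(self, om):
        data = benchmark_data("confounded", n_per_arm=500, seed=31)
        fs = fit_strategy(StrategySpec(om, outcome_model=om), data, seed=1)
        m0, m1 = fs.counterfactuals(data.X)
        assert np.all(np.isfinite(m0)) and np.all(np.isfinite(m1))
        assert np.all(m0 >= 0) and np.all(m1 >= 0)  # cumhaz scale

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="treatment model"):
            StrategySpec("bad", adjustment="ipw", outcome_model="arm_means").validate()
        with pytest.raises(ValueError, match="need a treatment or an outcome"):
            StrategySpec("bad2").validate()


class TestBalance:
    def test_identical_arms_perfectly_balanced(self, rng):
        n = 100
        X = pd.DataFrame({"x": rng.normal(size=n), "b": rng.integers(0, 2, n)})
        X2 = pd.concat([X, X], ignore_index=True)
        t = np.repeat([0, 1], n)
        br = balance_report(X2, t)
        np.testing.assert_allclose(br.table["smd"], 0.0, atol=1e-12)
        np.testing.assert_allclose(br.table["variance_ratio"], 1.0, atol=1e-12)
        assert br.asam == 0.0

    def test_binary_formula_against_moment_oracle(self, rng):
        # prevalences mirroring observed hypertension rates (0.312 vs 0.236)
        n1, n0 = 3932, 1452
        x1 = (np.arange(n1) < round(0.312 * n1)).astype(float)
        x0 = (np.arange(n0) < round(0.236 * n0)).astype(float)
        X = pd.DataFrame({"hypertension": np.concatenate([x0, x1])})
        t = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
        br = balance_report(X, t)
        p1, p0 = x1.mean(), x0.mean()
        expected = (p1 - p0) / np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2)
        assert br.table["smd"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_ipw_with_true_propensity_restores_balance(self):
        from scipy.special import expit

        data = benchmark_data("confounded", n_per_arm=2000, seed=12)
        raw = balance_report(data.X, data.treatment)
        e = expit(1.2 * data.X["comorbidity"].to_numpy())
        w = np.where(data.treatment == 1, 1 / e, 1 / (1 - e))
        weighted = balance_report(data.X, data.treatment, weights=w)
        assert raw.asam > 0.3
        assert weighted.asam < raw.asam
        assert weighted.asam < 0.1

    def test_zero_variance_flagging(self):
        X = pd.DataFrame({"c": [1.0, 1.0, 1.0, 1.0], "d": [1.0, 1.0, 2.0, 1.0]})
        t = np.array([0, 0, 1, 1])
        br = balance_report(X, t)
        row_c = br.table[br.table["covariate"] == "c"].iloc[0]
        assert row_c["smd"] == 0.0
        row_d = br.table[br.table["covariate"] == "d"].iloc[0]
        assert np.isinf(row_d["smd"]) or row_d["flag_smd"]
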