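import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import _oracles as orc
from conftest import make_tabular_cohort
from dosiomics_ntcp import modeling as mdl
from dosiomics_ntcp.modeling import (
    SURGERY,
    CohortData,
    FinalModel,
    SelectionFrequencies,
    auc_score,
    backward_eliminate,
    bootstrap_feature_selection,
    build_final_model,
    build_signature,
    evaluate,
    fit_final_coefficients,
    fit_logistic,
    refit_intercept,
    resolve_collinearity,
    univariable_screen,
    variance_inflation_factors,
)


def simple_cohort(X, y, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    feats = pd.DataFrame(X, columns=names)
    cov = pd.DataFrame({SURGERY: np.zeros(len(y), dtype=int)})
    return CohortData(feats, cov, y)


class TestLogisticCore:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(300, 3))
        eta = -1.0 + X @ np.array([0.8, -0.5, 0.2])
        y = (rng.random(300) < expit(eta)).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-4)
        assert fit.deviance == pytest.approx(-2 * ref.llf, abs=1e-6)

    def test_offset_enters_with_unit_coefficient(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=400)
        off = 0.5 * x
        y = (rng.random(400) < expit(-0.5 + off)).astype(float)
        fit = fit_logistic(np.empty((400, 0)), y, offset=off)
        ref = sm.GLM(
            y, np.ones((400, 1)), family=sm.families.Binomial(), offset=off
        ).fit()
        assert fit.beta[0] == pytest.approx(ref.params[0], abs=1e-6)


class TestUnivariableScreen:
    def test_perfect_predictor_retained(self):
        y = np.array([0, 0, 0, 1, 1, 1] * 10)
        cohort = simple_cohort(y[:, None].astype(float), y)
        survivors, info = univariable_screen(cohort, ["x0"])
        assert survivors == ["x0"]

    def test_constant_predictor_rejected(self, rng):
        y = (rng.random(100) < 0.3).astype(int)
        cohort = simple_cohort(np.ones((100, 1)), y)
        survivors, _ = univariable_screen(cohort, ["x0"])
        assert survivors == []

    def test_independent_predictors_rejected_at_threshold_rate(self):
        # p-values are uniform under the null, so alpha = 0.2 should reject
        # about 80%; assert >= 70% over 300 independent noise predictors
        rng = np.random.default_rng(42)
        n, k = 2000, 300
        y = (rng.random(n) < 0.3).astype(int)
        X = rng.normal(size=(n, k))
        cohort = simple_cohort(X, y)
        survivors, _ = univariable_screen(cohort, [f"x{i}" for i in range(k)])
        assert len(survivors) <= 0.3 * k

    def test_reports_sign_and_outcome_correlation(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1 + 2 * x)).astype(int)
        cohort = simple_cohort(x[:, None], y)
        survivors, info = univariable_screen(cohort, ["x0"])
        assert survivors == ["x0"]
        assert info.loc["x0", "slope"] > 0
        assert info.loc["x0", "spearman_outcome"] > 0


class TestCollinearity:
    def test_duplicate_dropped_keeping_outcome_correlated(self, rng):
        n = 300
        a = rng.normal(size=n)
        a_dup = a + 0.01 * rng.normal(size=n)
        b = rng.normal(size=n)
        y = (rng.random(n) < expit(-1 + 1.5 * a)).astype(int)
        cohort = simple_cohort(np.column_stack([a, a_dup, b]), y, ["a", "a_dup", "b"])
        kept = resolve_collinearity(cohort, ["a", "a_dup", "b"])
        assert "a" in kept and "a_dup" not in kept and "b" in kept

    def test_orthogonal_predictors_untouched(self, rng):
        X = rng.normal(size=(200, 4))
        y = (rng.random(200) < 0.3).astype(int)
        cohort = simple_cohort(X, y)
        names = [f"x{i}" for i in range(4)]
        assert resolve_collinearity(cohort, names) == names

    def test_pruned_set_satisfies_vif_bound(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))
        X[:, 1] = X[:, 0] + 0.05 * rng.normal(size=n)  # rho ~ 0.99
        y = (rng.random(n) < expit(-1 + X[:, 0])).astype(int)
        names = [f"x{i}" for i in range(5)]
        cohort = simple_cohort(X, y, names)
        kept = resolve_collinearity(cohort, names, vif_max=5.0)
        assert len(kept) < 5
        vif = variance_inflation_factors(cohort.matrix(kept))
        assert np.max(vif) <= 5.0

    def test_vif_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        X = rng.normal(size=(200, 4))
        X[:, 2] = 0.7 * X[:, 0] + 0.3 * rng.normal(size=200)
        Xc = sm.add_constant(X)
        ref = [variance_inflation_factor(Xc, i + 1) for i in range(4)]
        assert np.allclose(variance_inflation_factors(X), ref, rtol=1e-8)

    def test_single_predictor_returned_unchanged(self, rng):
        cohort = simple_cohort(rng.normal(size=(50, 1)), (rng.random(50) < 0.3).astype(int))
        assert resolve_collinearity(cohort, ["x0"]) == ["x0"]


class TestBackwardElimination:
    def test_true_feature_kept_across_replicates(self):
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 1000
            X = rng.normal(size=(n, 6))
            y = (rng.random(n) < expit(-2 + 1.0 * X[:, 0])).astype(int)
            cohort = simple_cohort(X, y)
            sig = backward_eliminate(cohort, [f"x{i}" for i in range(6)])
            hits += "x0" in sig
        assert hits >= 0.9 * reps

    def test_all_noise_mostly_empty(self):
        empties = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 1000
            X = rng.normal(size=(n, 5))
            y = (rng.random(n) < 0.2).astype(int)
            cohort = simple_cohort(X, y)
            sig = backward_eliminate(cohort, [f"x{i}" for i in range(5)])
            empties += len(sig) == 0
        # deletion p <= 0.01 is rare under the null
        assert empties >= 0.6 * reps

    def test_empty_candidates(self, rng):
        cohort = simple_cohort(rng.normal(size=(20, 1)), (rng.random(20) < 0.5).astype(int))
        assert backward_eliminate(cohort, []) == []


class TestBootstrapSelection:
    def test_single_bootstrap_deterministic(self):
        cohort = make_tabular_cohort(n=120, seed=3)
        names = list(cohort.features.columns)
        f1 = bootstrap_feature_selection(cohort, names, n_bootstrap=1, seed=9)
        f2 = bootstrap_feature_selection(cohort, names, n_bootstrap=1, seed=9)
        assert f1.counts == f2.counts
        assert all(v in (0, 1) for v in f1.counts.values())

    def test_strong_feature_selected_in_most_bootstraps(self):
        cohort = make_tabular_cohort(n=600, beta_true=1.5, seed=5)
        names = list(cohort.features.columns)
        freqs = bootstrap_feature_selection(cohort, names, n_bootstrap=200, seed=1)
        assert freqs.counts["f_true"] >= 0.8 * 200

    def test_noise_features_below_signature_threshold(self):
        cohort = make_tabular_cohort(n=500, beta_true=0.0, seed=11)
        names = list(cohort.features.columns)
        freqs = bootstrap_feature_selection(cohort, names, n_bootstrap=200, seed=2)
        assert max(freqs.counts.values()) < 200 / 4


class TestBuildSignature:
    def make_freq_cohort(self, rng, counts, B=1000):
        names = list(counts)
        X = rng.normal(size=(200, len(names)))
        y = (rng.random(200) < 0.3).astype(int)
        cohort = simple_cohort(X, y, names)
        return SelectionFrequencies(dict(counts), B), cohort

    def test_quarter_threshold(self, rng):
        freqs, cohort = self.make_freq_cohort(rng, {"A": 300, "B": 100})
        assert build_signature(freqs, cohort) == ["A", SURGERY]

    def test_most_selected_fallback(self, rng):
        freqs, cohort = self.make_freq_cohort(rng, {"A": 100, "B": 90})
        assert build_signature(freqs, cohort) == ["A", SURGERY]

    def test_collinear_pair_pruned_from_final_signature(self, rng):
        n = 300
        a = rng.normal(size=n)
        a_dup = a + 0.02 * rng.normal(size=n)
        y = (rng.random(n) < expit(-1 + a)).astype(int)
        cohort = simple_cohort(np.column_stack([a, a_dup]), y, ["A", "A_dup"])
        freqs = SelectionFrequencies({"A": 260, "A_dup": 255}, 1000)
        sig = build_signature(freqs, cohort)
        assert sig.count(SURGERY) == 1
        assert ("A" in sig) != ("A_dup" in sig)  # exactly one survives


class TestFinalCoefficients:
    def test_single_bootstrap_equals_direct_fit(self):
        cohort = make_tabular_cohort(n=200, seed=8)
        sig = ["f_true", SURGERY]
        coefs, _ = fit_final_coefficients(cohort, sig, n_bootstrap=1, seed=4)
        idx = mdl._bootstrap_indices(cohort.outcome, 4, 2, 0)
        sub = cohort.subset(idx)
        ref = fit_logistic(sub.matrix(sig), sub.outcome.astype(float))
        assert coefs["f_true"] == pytest.approx(ref.beta[1], abs=1e-9)

    def test_recovers_generative_coefficient(self):
        cohort = make_tabular_cohort(
            n=2000, n_noise=0, beta_true=1.5, beta_surgery=0.0, seed=21
        )
        coefs, med_p = fit_final_coefficients(
            cohort, ["f_true", SURGERY], n_bootstrap=200, seed=3
        )
        assert coefs["f_true"] == pytest.approx(1.5, abs=0.25)
        assert med_p["f_true"] < 0.001

    def test_zero_coefficient_gives_unit_odds_ratio(self):
        model = FinalModel(
            signature=["a"], coefficients={"a": 0.0}, intercept=-1.0,
            median_p={"a": 1.0}, n_bootstrap=1, seed=0,
        )
        assert model.odds_ratios["a"] == 1.0


class TestInterceptRefit:
    def test_null_model_closed_form(self, rng):
        n = 500
        y = np.zeros(n, dtype=int)
        y[:100] = 1  # event rate 0.2
        cohort = simple_cohort(rng.normal(size=(n, 1)), y)
        b0 = refit_intercept(cohort, {"x0": 0.0})
        assert b0 == pytest.approx(logit(0.2), abs=1e-4)

    def test_score_identity_mean_prediction_equals_event_rate(self):
        cohort = make_tabular_cohort(n=300, seed=13)
        coefs = {"f_true": 1.2, SURGERY: 0.5}
        b0 = refit_intercept(cohort, coefs)
        eta = cohort.matrix(list(coefs)) @ np.array(list(coefs.values()))
        assert np.mean(expit(b0 + eta)) == pytest.approx(
            cohort.outcome.mean(), abs=1e-8
        )

    def test_matches_dense_grid_search(self):
        cohort = make_tabular_cohort(n=250, seed=17)
        coefs = {"f_true": 1.0}
        b0 = refit_intercept(cohort, coefs)
        eta = cohort.column("f_true") * 1.0
        grid = np.linspace(-10, 10, 20001)
        y = cohort.outcome.astype(float)
        p = expit(grid[:, None] + eta[None, :])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        nll = -(y[None, :] * np.log(p) + (1 - y[None, :]) * np.log(1 - p)).sum(axis=1)
        assert b0 == pytest.approx(grid[np.argmin(nll)], abs=2e-3)


class TestEvaluation:
    def make_model(self, coefs, intercept):
        return FinalModel(
            signature=list(coefs), coefficients=dict(coefs), intercept=intercept,
            median_p={k: 0.5 for k in coefs}, n_bootstrap=1, seed=0,
        )

    def test_perfect_separation_auc_one(self):
        y = np.array([0] * 10 + [1] * 10)
        x = y.astype(float)
        cohort = simple_cohort(x[:, None], y)
        rep = evaluate(self.make_model({"x0": 3.0}, -1.5), cohort)
        assert rep.auc == 1.0

    def test_uninformative_predictor_auc_half(self):
        rng = np.random.default_rng(99)
        n = 2000
        y = (rng.random(n) < 0.3).astype(int)
        x = rng.normal(size=n)
        cohort = simple_cohort(x[:, None], y)
        rep = evaluate(self.make_model({"x0": 1.0}, -1.0), cohort)
        assert rep.auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_bruteforce_with_ties(self, rng):
        n = 50
        y = (rng.random(n) < 0.4).astype(int)
        y[0], y[1] = 1, 0
        score = rng.integers(0, 8, size=n).astype(float)  # many ties
        assert auc_score(y, score) == pytest.approx(orc.auc_brute(y, score), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 200
        y = (rng.random(n) < 0.3).astype(int)
        y[0], y[1] = 1, 0
        score = rng.normal(size=n)
        assert auc_score(y, score) == pytest.approx(roc_auc_score(y, score), abs=1e-12)

    def test_selffit_model_perfectly_calibrated(self):
        # jointly MLE-fit slopes+intercept: calibration slope 1, intercept 0
        cohort = make_tabular_cohort(n=400, seed=31)
        sig = ["f_true", SURGERY]
        fit = fit_logistic(cohort.matrix(sig), cohort.outcome.astype(float))
        model = self.make_model(dict(zip(sig, fit.beta[1:])), fit.beta[0])
        rep = evaluate(model, cohort)
        assert rep.cal_slope == pytest.approx(1.0, abs=1e-6)
        assert rep.cal_intercept == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_constant_predictor(self, rng):
        y = (rng.random(60) < 0.4).astype(int)
        cohort = simple_cohort(np.ones((60, 1)), y)
        with pytest.warns(UserWarning, match="degenerate"):
            rep = evaluate(self.make_model({"x0": 1.0}, 0.0), cohort)
        assert rep.auc == 0.5
        assert rep.cal_slope == 0.0

    def test_representation_mismatch_raises(self):
        cohort = make_tabular_cohort(n=60, seed=1)
        cohort.representation = "bed2"
        model = self.make_model({"f_true": 1.0}, -1.0)
        model.representation = "bed3"
        with pytest.raises(ValueError, match="representation mismatch"):
            evaluate(model, cohort)


class TestDeterminismAndSerialization:
    def test_identical_seed_gives_identical_model_json(self, tmp_path):
        cohort = make_tabular_cohort(n=250, seed=2)
        names = list(cohort.features.columns)
        m1, _ = build_final_model(cohort, names, n_bootstrap=40, seed=5)
        m2, _ = build_final_model(cohort, names, n_bootstrap=40, seed=5)
        assert m1.to_json() == m2.to_json()

    def test_json_round_trip(self, tmp_path):
        cohort = make_tabular_cohort(n=150, seed=6)
        m, _ = build_final_model(cohort, list(cohort.features.columns), n_bootstrap=20, seed=1)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = FinalModel.from_json(path)
        assert m2.signature == m.signature
        assert m2.coefficients == m.coefficients
        assert m2.intercept == m.intercept
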