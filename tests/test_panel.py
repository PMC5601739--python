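"""Logistic panel: IRLS fit, stepwise selection, performance, validation."""

import numpy as np
import pytest
from scipy import optimize

from pepdiscover.panel import (
    ModelError,
    PanelModel,
    SeparationError,
    evaluate,
    external_validate,
    fit_logistic,
    odds_ratios,
    predict_prob,
    stepwise_select,
)
from pepdiscover.synthetic import features_to_matrix, generate_panel_features


def _nll(params, X1, y):
    eta = X1 @ params
    return -(y @ eta - np.logaddexp(0.0, eta).sum())


class TestFitLogistic:
    def test_binary_predictor_recovers_log_odds_ratio(self):
        # exposure/outcome table (15,5 / 5,15): beta = ln(15*15/(5*5)) = ln 9
        X = np.repeat([1.0, 1.0, 0.0, 0.0], [15, 5, 5, 15])[:, None]
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [15, 5, 5, 15])
        fit = fit_logistic(X, y)
        assert fit.beta[0] == pytest.approx(np.log(9.0), abs=1e-6)

    def test_symmetric_design_gives_zero_intercept(self, rng):
        x = rng.normal(0, 1, size=3000)
        y = (rng.random(3000) < 1 / (1 + np.exp(-1.2 * x))).astype(float)
        fit = fit_logistic(x[:, None], y)
        assert abs(fit.intercept) < 3 * fit.se[0]

    def test_parameter_recovery_within_joint_confidence_bounds(self):
        n, beta_true, intercept_true = 2000, np.array([0.5, -0.3]), 0.2
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, size=(n, 2))
        eta = intercept_true + X @ beta_true
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        # 2.6 se per coefficient keeps ~97% joint coverage over 3 parameters
        for est, se, truth in zip(fit.params, fit.se,
                                  [intercept_true, *beta_true]):
            assert abs(est - truth) < 2.6 * se

    def test_matches_newton_oracle_loglik(self, rng):
        """Independent check: scipy BFGS optimum of the same likelihood."""
        for k in (1, 2, 3):
            X = rng.normal(0, 1, size=(60, k))
            y = (rng.random(60) < 0.5).astype(float)
            fit = fit_logistic(X, y)
            X1 = np.column_stack([np.ones(60), X])
            res = optimize.minimize(_nll, np.zeros(k + 1), args=(X1, y),
                                    method="BFGS", options={"gtol": 1e-10})
            assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(0, 1, size=(80, 2))
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.3 + X @ [0.8, -0.5])))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_perfect_separation_raises(self):
        X = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        y = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_constant_column_rejected(self):
        X = np.ones((20, 1))
        y = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.raises(ModelError, match="constant"):
            fit_logistic(X, y)


class TestStepwise:
    def test_recovers_informative_drops_noise(self):
        X, y, informative = generate_panel_features(200, seed=0)
        model = stepwise_select(features_to_matrix(X, y),
                                [float(c) for c in X.columns])
        selected = {f"{mz:.1f}" for mz in model.peak_mzs}
        assert len(selected & set(informative)) >= 4
        assert len(selected - set(informative)) <= 1

    def test_unreachable_entry_threshold_gives_intercept_only(self):
        X, y, _ = generate_panel_features(120, seed=2)
        with pytest.warns(UserWarning, match="intercept-only"):
            model = stepwise_select(features_to_matrix(X, y),
                                    [float(c) for c in X.columns],
                                    p_enter=1e-12, p_remove=0.1)
        assert model.peak_mzs == []
        p0 = y.mean()
        assert model.intercept == pytest.approx(np.log(p0 / (1 - p0)), abs=1e-9)

    def test_deterministic(self):
        X, y, _ = generate_panel_features(150, seed=4)
        pm = features_to_matrix(X, y)
        cands = [float(c) for c in X.columns]
        m1 = stepwise_select(pm, cands)
        m2 = stepwise_select(pm, cands)
        assert m1.peak_mzs == m2.peak_mzs
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_no_retained_coefficient_above_removal_threshold(self):
        for seed in (0, 3, 5):
            X, y, _ = generate_panel_features(200, seed=seed)
            model = stepwise_select(features_to_matrix(X, y),
                                    [float(c) for c in X.columns])
            if model.peak_mzs:
                assert model.p_wald.max() <= 0.10

    def test_panel_auc_dominates_each_member_auc(self):
        from pepdiscover.univariate import roc_auc

        X, y, _ = generate_panel_features(200, seed=1)
        pm = features_to_matrix(X, y)
        model = stepwise_select(pm, [float(c) for c in X.columns])
        probs = predict_prob(model, pm)
        panel_auc, _ = roc_auc(probs, y)
        for mz, beta in zip(model.peak_mzs, model.beta):
            col = pm.column(mz, tol_rel=1e-6)
            auc, _ = roc_auc(col if beta > 0 else -col, y)
            assert panel_auc >= auc - 1e-9


class TestOddsRatios:
    @pytest.mark.parametrize("beta,expected_or", [(0.104, 1.110), (0.180, 1.197),
                                                  (-0.525, 0.592), (0.0, 1.000)])
    def test_or_is_exp_beta_to_three_decimals(self, beta, expected_or):
        model = PanelModel([1000.0], np.array([beta]), 0.0, np.array([0.05]), 0.1)
        table = odds_ratios(model)
        assert table.OR.iloc[0] == pytest.approx(expected_or, abs=5e-4)

    def test_ci_geometric_mean_equals_or(self):
        model = PanelModel([1000.0, 2000.0], np.array([0.3, -0.8]), 0.0,
                           np.array([0.1, 0.2]), 0.1)
        ci = model.or_ci
        np.testing.assert_allclose(np.sqrt(ci[:, 0] * ci[:, 1]), model.or_, rtol=1e-9)

    def test_zero_beta_ci_symmetric_about_one_on_log_scale(self):
        model = PanelModel([1000.0], np.array([0.0]), 0.0, np.array([0.2]), 0.1)
        lo, hi = model.or_ci[0]
        assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-12)


class TestPredictProb:
    def _model(self):
        return PanelModel([1500.0], np.array([1.0]), 0.0, np.array([0.1]), 0.1)

    def test_zero_intensities_give_logistic_of_intercept(self):
        X, y, _ = generate_panel_features(50, seed=3)
        pm = features_to_matrix(X * 0.0, y)
        model = PanelModel([float(X.columns[0])], np.array([2.0]), -1.0,
                           np.array([0.1]), 0.1)
        probs = predict_prob(model, pm)
        np.testing.assert_allclose(probs, 1 / (1 + np.exp(1.0)))

    def test_increasing_up_peak_never_decreases_probability(self):
        X, y, _ = generate_panel_features(50, seed=3)
        pm = features_to_matrix(X, y)
        model = PanelModel([float(X.columns[0])], np.array([0.5]), 0.0,
                           np.array([0.1]), 0.1)
        base = predict_prob(model, pm)
        pm_up = features_to_matrix(
            X.assign(**{X.columns[0]: X[X.columns[0]] + 10.0}), y)
        up = predict_prob(model, pm_up)
        assert (up >= base - 1e-15).all()

    def test_missing_model_peak_warns_and_uses_zeros(self):
        X, y, _ = generate_panel_features(50, seed=3)
        pm = features_to_matrix(X, y)
        model = PanelModel([9999.0], np.array([1.0]), 0.25, np.array([0.1]), 0.1)
        with pytest.warns(UserWarning, match="missing"):
            probs = predict_prob(model, pm)
        np.testing.assert_allclose(probs, 1 / (1 + np.exp(-0.25)))


class TestEvaluate:
    def test_printed_discovery_confusion_matrix(self):
        pred = np.repeat([1, 0, 1, 0], [96, 4, 5, 95])
        truth = np.repeat([1, 1, 0, 0], [96, 4, 5, 95])
        perf = evaluate(pred, truth)
        assert perf.accuracy == pytest.approx(0.955)
        assert perf.sensitivity == pytest.approx(0.960)
        assert perf.specificity == pytest.approx(0.950)

    def test_printed_validation_confusion_matrix(self):
        pred = np.repeat([1, 0, 1, 0], [87, 4, 11, 80])
        truth = np.repeat([1, 1, 0, 0], [87, 4, 11, 80])
        perf = evaluate(pred, truth)
        assert perf.accuracy == pytest.approx(167 / 182)
        assert perf.sensitivity == pytest.approx(87 / 91)
        assert perf.specificity == pytest.approx(80 / 91)

    def test_perfect_prediction_degenerate_intervals(self):
        truth = np.repeat([1, 0], [10, 10])
        perf = evaluate(truth, truth)
        assert (perf.accuracy, perf.sensitivity, perf.specificity) == (1.0, 1.0, 1.0)
        assert perf.sens_ci == (1.0, 1.0)
        assert perf.spec_ci == (1.0, 1.0)

    def test_string_labels_accepted(self):
        pred = np.array(["case", "control", "case", "control"])
        truth = np.array(["case", "case", "control", "control"])
        perf = evaluate(pred, truth)
        assert (perf.tp, perf.fn, perf.fp, perf.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            evaluate(np.array([1, 0]), np.array([1, 0, 1]))


class TestExternalValidate:
    def test_self_validation_reproduces_training_performance(self):
        X, y, _ = generate_panel_features(150, seed=6)
        pm = features_to_matrix(X, y)
        model = stepwise_select(pm, [float(c) for c in X.columns])
        a = external_validate(model, pm)
        b = external_validate(model, pm)
        assert a == b

    def test_exchangeable_cohort_accuracy_close_to_training(self):
        X, y, _ = generate_panel_features(200, seed=0)
        pm = features_to_matrix(X, y)
        model = stepwise_select(pm, [float(c) for c in X.columns])
        Xv, yv, _ = generate_panel_features(500, seed=1000)
        train = external_validate(model, pm)
        val = external_validate(model, features_to_matrix(Xv, yv, "val"))
        assert abs(train.accuracy - val.accuracy) <= 0.05

    def test_permuted_labels_auc_near_half(self):
        X, y, _ = generate_panel_features(200, seed=8)
        pm = features_to_matrix(X, y)
        model = stepwise_select(pm, [float(c) for c in X.columns])
        rng = np.random.default_rng(99)
        y_perm = rng.permutation(y)
        perf = external_validate(model, features_to_matrix(X, y_perm, "perm"))
        # binomial-scale noise around 0.5 for n=200
        assert abs(perf.auc - 0.5) < 0.12

    def test_model_json_round_trip(self, tmp_path):
        X, y, _ = generate_panel_features(150, seed=6)
        pm = features_to_matrix(X, y)
        model = stepwise_select(pm, [float(c) for c in X.columns])
        model.to_json(tmp_path / "model.json", provenance={"note": "test"})
        back = PanelModel.from_json(tmp_path / "model.json")
        assert back.peak_mzs == model.peak_mzs
        np.testing.assert_allclose(back.beta, model.beta)
        assert external_validate(back, pm) == external_validate(model, pm)
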