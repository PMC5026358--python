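"""Accuracy models, probit fitting, and Weber-fraction estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.stats import spearmanr

from ansacuity.psychomodels import (
    fit_probit_glm,
    fit_weber,
    lr_test_predictor,
    predict_accuracy_linear,
    predict_accuracy_log,
    predict_choose_right_log,
    predict_choose_right_modlog,
    weber_predictor_linear,
    weber_predictor_log,
)
from ansacuity.synthetic import GeneratorConfig, generate_accuracy_only
from conftest import DESIGN_RATIOS, make_bernoulli_trials


class TestPredictions:
    def test_linear_model_values(self):
        assert predict_accuracy_linear(1.0, 0.3) == pytest.approx(0.5)
        # oracle: direct normal-CDF evaluation of the closed form
        assert predict_accuracy_linear(2.0, 0.5) == pytest.approx(
            stats.norm.cdf(1.0 / (0.5 * np.sqrt(5.0))), abs=1e-12
        )
        assert predict_accuracy_linear(2.0, 1e-9) == pytest.approx(1.0)

    def test_log_model_values(self):
        from scipy.special import erf

        assert predict_choose_right_log(1.0, 0.4) == pytest.approx(0.5)
        assert predict_choose_right_log(2.0, 0.5) == pytest.approx(
            0.5 + 0.5 * erf(1.0), abs=1e-12
        )

    @given(r=st.floats(0.05, 20.0), w=st.floats(0.05, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_linear_prediction_reciprocal_invariance(self, r, w):
        assert predict_accuracy_linear(r, w) == pytest.approx(
            predict_accuracy_linear(1.0 / r, w), rel=1e-12
        )

    @given(r=st.floats(0.05, 20.0), w=st.floats(0.05, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_log_choice_antisymmetry(self, r, w):
        total = predict_choose_right_log(r, w) + predict_choose_right_log(1.0 / r, w)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_predictions_decrease_in_w_and_increase_in_ratio_strength(self):
        ws = np.linspace(0.1, 1.5, 20)
        assert np.all(np.diff(predict_accuracy_linear(2.0, ws)) < 0)
        assert np.all(np.diff(predict_accuracy_log(2.0, ws)) < 0)
        rs = np.linspace(1.05, 4.0, 20)
        assert np.all(np.diff(predict_accuracy_linear(rs, 0.5)) > 0)
        assert np.all(np.diff(predict_accuracy_log(rs, 0.5)) > 0)

    def test_modlog_reduces_to_log_model(self):
        r_num = np.array([0.5, 0.8, 1.25, 2.0])
        w = 0.45
        beta_num = 1.0 / (np.sqrt(2.0) * w)
        reduced = predict_choose_right_modlog(r_num, 0.0, 0.0, 0.0, beta_num, 0.0, 0.0)
        assert np.allclose(reduced, predict_choose_right_log(r_num, w), atol=1e-12)
        assert predict_choose_right_modlog(1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0) == (
            pytest.approx(stats.norm.cdf(1.0))
        )

    def test_invalid_w_rejected(self):
        with pytest.raises(ValueError):
            predict_accuracy_linear(2.0, -0.1)
        with pytest.raises(ValueError):
            predict_choose_right_log(2.0, 0.0)


class TestPredictors:
    def test_linear_predictor_value_and_symmetry(self):
        assert weber_predictor_linear(0.5) == pytest.approx(0.5 / np.sqrt(1.25))
        assert weber_predictor_linear(2.0) == pytest.approx(0.5 / np.sqrt(1.25))
        assert weber_predictor_log(2.0) == pytest.approx(1.0)
        assert weber_predictor_linear(0.999999) == pytest.approx(0.0, abs=1e-5)

    def test_linear_and_log_predictors_rank_identically_over_design_ratios(self):
        """Both predictors are strictly monotone in R: Spearman rho exactly 1."""
        R = np.asarray(DESIGN_RATIOS)
        lin = weber_predictor_linear(R)
        log = weber_predictor_log(1.0 / R)
        rho, _ = spearmanr(lin, log)
        assert rho == pytest.approx(1.0, abs=1e-12)


class TestGlmFitting:
    def test_constant_outcome_flagged_not_fitted(self):
        fit = fit_probit_glm(np.ones(50), np.linspace(0, 1, 50), has_intercept=False)
        assert not fit.converged

    def test_slope_recovery_against_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10_000)
        y = (rng.random(10_000) < stats.norm.cdf(2.0 * x)).astype(float)
        fit = fit_probit_glm(y, x, has_intercept=False)
        # coarse grid maximizing the Bernoulli likelihood, independent of IRLS
        grid = np.linspace(0.5, 4.0, 351)
        ll = [
            np.sum(np.log(np.clip(stats.norm.cdf(b * x) * y
                                  + (1 - stats.norm.cdf(b * x)) * (1 - y), 1e-12, 1)))
            for b in grid
        ]
        b_grid = grid[int(np.argmax(ll))]
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(b_grid, abs=0.02)
        assert abs(fit.coefficients[0] - 2.0) < 3 * fit.standard_errors[0]

    def test_null_logit_loglik_closed_form(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        fit = fit_probit_glm(y, np.zeros((100, 0)), has_intercept=True, link="logit")
        assert fit.log_likelihood == pytest.approx(100 * np.log(0.5), rel=1e-9)


class TestWeberFit:
    def test_deterministic_counts_recover_w(self, item_set):
        """Responses set to round(80 p) correct per ratio recover w = 0.3."""
        w_true = 0.3
        rows = []
        for ratio in DESIGN_RATIOS:
            p = predict_accuracy_linear(1.0 / ratio, w_true)
            n_correct = int(round(80 * p))
            rows += [(ratio, True)] * n_correct + [(ratio, False)] * (80 - n_correct)
        n_small = {0.5: 10, 0.6: 12, 0.7: 14, 0.8: 16, 0.9: 18}
        df = pd.DataFrame(
            {
                "participant_id": "P1",
                "experiment": "synthetic",
                "condition": "c",
                "n_left": [n_small[r] for r, _ in rows],
                "n_right": [round(n_small[r] / r) for r, _ in rows],
                "response_side": ["right" if c else "left" for _, c in rows],
                "correct": [c for _, c in rows],
                "rt_ms": 500.0,
            }
        )
        fit = fit_weber(df, "linear")
        assert fit.converged and not fit.excluded
        assert fit.w == pytest.approx(w_true, abs=0.02)
        # 1-D likelihood grid search oracle over w
        grid = np.linspace(0.05, 2.0, 1951)
        ratio = np.array([r for r, _ in rows])
        y = np.array([c for _, c in rows], dtype=float)
        best = None
        for w in grid:
            p = predict_accuracy_linear(1.0 / ratio, w)
            ll = np.sum(np.log(np.clip(p * y + (1 - p) * (1 - y), 1e-12, 1)))
            if best is None or ll > best[1]:
                best = (w, ll)
        assert fit.w == pytest.approx(best[0], rel=0.01)

    def test_chance_responses_excluded(self, item_set):
        rng = np.random.default_rng(7)
        trials = make_bernoulli_trials(lambda r: np.full_like(r, 0.5), item_set, rng)
        # decouple choice from correctness entirely
        fit = fit_weber(trials, "linear")
        assert fit.excluded
        assert fit.beta_p >= 0.05 or fit.beta <= 0 or not fit.converged

    def test_linear_and_log_w_rank_cohorts_identically(self, accuracy_cohort):
        """Different w scales, identical ranking across a cohort."""
        ws = {"linear": [], "log": []}
        for _, grp in accuracy_cohort.groupby("participant_id"):
            for model in ("linear", "log"):
                fit = fit_weber(grp, model)
                ws[model].append(fit.w)
        ok = np.isfinite(ws["linear"]) & np.isfinite(ws["log"])
        rho, _ = spearmanr(np.asarray(ws["linear"])[ok], np.asarray(ws["log"])[ok])
        assert rho >= 0.99

    def test_modlog_recovers_visual_betas_via_lr_test(self):
        cfg = GeneratorConfig(
            n_participants=1, w_mean=0.5, w_sd=0.0, beta_size=0.5,
            congruency_mix=0.5, trials_per_ratio=1000, seed=31,
        )
        trials = generate_accuracy_only(cfg, "eq4_modlog")
        y = (trials["response_side"] == "right").to_numpy(dtype=float)
        X_full = np.column_stack(
            [np.log2(trials["r_num"]), trials["log2_r_size"], trials["log2_r_spacing"]]
        )
        full = fit_probit_glm(y, X_full, has_intercept=True)
        reduced = fit_probit_glm(y, X_full[:, [0, 2]], has_intercept=True)
        chi2, df, p = lr_test_predictor(full, reduced)
        assert df == 1
        assert p < 0.001

    def test_lr_test_identical_models_is_null(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = (rng.random(200) < stats.norm.cdf(x)).astype(float)
        fit = fit_probit_glm(y, x, has_intercept=True)
        chi2, df, p = lr_test_predictor(fit, fit)
        assert (chi2, df, p) == (0.0, 0, 1.0)
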