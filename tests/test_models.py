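"""CPT scaling, logistic fit identities, quadratic vertex analytics."""

import numpy as np
import pandas as pd
import pytest

from cprstress import (
    QuadraticFit,
    ValidationError,
    fit_linear,
    fit_logistic,
    fit_quadratic,
    label_high_performance,
    predict_quadratic,
    scale_cpt,
)


class TestScaling:
    @pytest.mark.parametrize(
        "raw,maxr,expected", [(20, 20, 10.0), (0, 20, 0.0), (15, 20, 7.5)]
    )
    def test_scale_cpt(self, raw, maxr, expected):
        assert scale_cpt(raw, maxr) == expected

    def test_raw_above_max_rejected(self):
        with pytest.raises(ValidationError):
            scale_cpt(21, 20)

    @pytest.mark.parametrize(
        "score,flag", [(7.5, False), (9.17, True), (0.0, False), (7.51, True)]
    )
    def test_high_performance_strict_cut(self, score, flag):
        assert label_high_performance(score) is flag


class TestLogistic:
    def test_intercept_only_closed_form(self):
        feats = pd.DataFrame({"y": [1, 1, 0, 0]})
        fit = fit_logistic(feats, [], outcome="y")
        assert fit.log_likelihood == pytest.approx(4 * np.log(0.5))
        assert fit.aic == pytest.approx(2 - 8 * np.log(0.5))
        assert fit.mcfadden_r2 == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_binary_predictor_slope_is_log_odds_ratio(self):
        # x=0: 5 successes / 10 failures; x=1: 10 successes / 5 failures
        y = [1] * 5 + [0] * 10 + [1] * 10 + [0] * 5
        x = [0.0] * 15 + [1.0] * 15
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
        assert fit.coefficients["x"] == pytest.approx(np.log(4.0), abs=1e-5)

    def test_identities_hold_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        y = (x + rng.standard_normal(60) > 0).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
        assert fit.mcfadden_r2 == pytest.approx(
            1 - fit.log_likelihood / fit.null_log_likelihood
        )
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_likelihood)
        assert 0 <= fit.mcfadden_r2 < 1

    def test_null_mcfadden_near_zero(self):
        rng = np.random.default_rng(42)
        vals = []
        for _ in range(100):
            x = rng.standard_normal(40)
            y = (rng.uniform(size=40) > 0.5).astype(int)
            if y.min() == y.max():
                continue
            vals.append(
                fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y").mcfadden_r2
            )
        assert np.mean(vals) < 0.05

    def test_accuracy_at_least_majority_class(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal(30)
            y = (0.5 * x + rng.standard_normal(30) > 0.3).astype(int)
            if y.min() == y.max():
                continue
            fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
            if fit.converged and not fit.separation:
                assert fit.accuracy >= max(np.mean(y), 1 - np.mean(y)) - 1e-12

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0], "y": [1, 1]}), ["x"], outcome="y")

    def test_separation_flagged(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = (x > 0).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
        assert fit.separation


class TestQuadratic:
    def test_exact_three_point_fit(self):
        fit = fit_quadratic([0.0, 1.0, 2.0], [1.0, 3.0, 1.0])
        assert fit.a == pytest.approx(-2.0)
        assert fit.b == pytest.approx(4.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.vertex_x == pytest.approx(1.0)
        assert fit.vertex_y == pytest.approx(3.0)

    def test_constant_y_convention(self):
        fit = fit_quadratic([0.0, 1.0, 2.0, 3.0], [4.0, 4.0, 4.0, 4.0])
        assert fit.a == fit.b == 0.0
        assert fit.r2 == 0.0
        assert fit.degenerate

    def test_vertex_from_reported_coefficients(self):
        # the reported regression coefficients put the optimum at SD1 = 0.0201 s
        fit = QuadraticFit(a=-15748.2, b=631.81, intercept=2.88, r2=1.0)
        assert round(fit.vertex_x, 4) == 0.0201
        assert fit.vertex_y == pytest.approx(2.88 + 631.81**2 / (4 * 15748.2))

    def test_convex_fit_has_no_vertex(self):
        fit = fit_quadratic([0.0, 1.0, 2.0], [1.0, -1.0, 1.0])
        assert fit.a > 0
        assert fit.vertex_x is None

    def test_collinear_design_rejected(self):
        with pytest.raises(ValidationError):
            fit_quadratic([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_parameter_recovery_improves_with_dyads(self):
        a, b, c = -15748.2, 631.81, 2.88
        errs = []
        for n in (20, 500):
            rng = np.random.default_rng(42)
            x = rng.normal(0.03, 0.012, n)
            y = a * x**2 + b * x + c + rng.normal(0, 0.3, n)
            fit = fit_quadratic(x, y)
            errs.append(abs(fit.a - a) / abs(a))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05

    def test_prediction_symmetry_about_vertex(self):
        fit = QuadraticFit(a=-2.0, b=4.0, intercept=1.0, r2=1.0)
        assert predict_quadratic(fit, 0.0) == pytest.approx(1.0)
        assert predict_quadratic(fit, 2.0) == pytest.approx(1.0)
        for d in (0.1, 0.5, 1.7):
            assert predict_quadratic(fit, fit.vertex_x + d) == pytest.approx(
                predict_quadratic(fit, fit.vertex_x - d)
            )
        assert predict_quadratic(fit, fit.vertex_x) == pytest.approx(fit.vertex_y)


class TestLinear:
    def test_exact_line(self):
        fit = fit_linear([0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_symmetric_inverted_u_defeats_linear_model(self):
        # symmetric concave data: slope exactly 0 while the quadratic is exact
        x = np.linspace(-0.02, 0.02, 9) + 0.0201
        y = -15748.2 * (x - 0.0201) ** 2 + 9.17
        lin = fit_linear(x, y)
        quad = fit_quadratic(x, y)
        assert abs(lin.slope) < 1e-8
        assert lin.r2 == pytest.approx(0.0, abs=1e-12)
        assert quad.r2 == pytest.approx(1.0)

    def test_slope_p_uniform_under_null(self):
        rng = np.random.default_rng(42)
        ps = [
            fit_linear(rng.standard_normal(25), rng.standard_normal(25)).slope_pvalue
            for _ in range(400)
        ]
        # uniform on (0,1): check mean and the 5% rejection rate
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValidationError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDyadFeatures:
    def test_features_from_cohort(self, small_cohort, truth_table):
        from cprstress import build_dyad_features

        feats = build_dyad_features(truth_table, small_cohort.dyads)
        assert len(feats) == 4
        assert set(feats.columns) >= {
            "tm_eda_pre", "tl_eda_pre", "tl_scr_pre", "dyad_sd1",
            "cpt_score", "high_performance",
        }
        # dyad SD1 equals the generator's dyad mean
        truth = small_cohort.truth.dyad_truth.set_index("dyad_id")
        for _, row in feats.iterrows():
            assert row.dyad_sd1 == pytest.approx(truth.loc[row.dyad_id, "dyad_sd1"])
            assert row.cpt_score == pytest.approx(
                truth.loc[row.dyad_id, "cpt_score"], abs=1e-9
            )
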