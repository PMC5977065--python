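"""Quadratic surface fitting, ANOVA diagnostics, pruning, prediction."""

import numpy as np
import pytest

import extractopt as xo
from extractopt.rsm import TERM_NAMES, SingularDesignError


class TestExpandQuadratic:
    def test_center_point_basis(self):
        basis = xo.expand_quadratic(np.zeros(4))
        assert basis[0] == 1.0
        assert np.all(basis[1:] == 0.0)

    def test_sign_arithmetic(self):
        basis = xo.expand_quadratic(np.array([1.0, 1.0, -1.0, 1.0]))
        # interactions x1x2, x1x3, x1x4, x2x3, x2x4, x3x4
        assert list(basis[5:11]) == [1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
        assert list(basis[11:]) == [1.0, 1.0, 1.0, 1.0]

    def test_dot_with_reduced_surface(self, reduced_surface):
        """The published polynomial evaluated at its reported optimum."""
        basis = xo.expand_quadratic(np.array([0.722, 0.0, 2.0, -2.0]))
        coefs = np.where(reduced_surface.term_active, reduced_surface.coefficients, 0.0)
        assert round(float(basis @ coefs), 3) == 427.156

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            xo.expand_quadratic(np.array([np.inf, 0, 0, 0]))


class TestFitQuadratic:
    def test_reproduces_published_coefficients(self, full_fit):
        model, _ = full_fit
        named = dict(zip(TERM_NAMES, model.coefficients))
        assert round(named["intercept"], 2) == 365.45
        assert round(named["x1"], 2) == 11.92
        assert round(named["x3"], 2) == 11.95
        assert round(named["x4"], 2) == 11.45
        assert round(named["x3:x4"], 1) == -14.1
        assert round(named["x1^2"], 2) == -8.25
        assert round(named["x2^2"], 2) == -9.68

    def test_noiseless_recovery_is_exact(self, study_factors, rng):
        truth = xo.QuadraticModel(rng.normal(0, 5, 15))
        design = xo.build_ccd(study_factors)
        design = design.with_responses(truth.predict(design.coded) + 400.0)
        shifted = truth.coefficients.copy()
        shifted[0] += 400.0
        fitted = xo.fit_quadratic(design)
        assert np.allclose(fitted.coefficients, shifted, atol=1e-9)

    def test_orthogonality_shortcut_matches_ols(self, study_data, full_fit):
        """For a CCD the linear/interaction estimates have closed forms:
        a_i = sum(x_i y)/sum(x_i^2) and a_ij = sum(x_i x_j y)/16."""
        model, _ = full_fit
        X = study_data.coded
        y = study_data.responses
        named = dict(zip(TERM_NAMES, model.coefficients))
        for i in range(4):
            shortcut = (X[:, i] * y).sum() / (X[:, i] ** 2).sum()
            assert named[f"x{i + 1}"] == pytest.approx(shortcut, abs=1e-9)
        pairs = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
        for i, j in pairs:
            col = X[:, i - 1] * X[:, j - 1]
            shortcut = (col * y).sum() / 16.0
            assert named[f"x{i}:x{j}"] == pytest.approx(shortcut, abs=1e-9)

    def test_rank_deficiency_reported(self, study_data):
        short = xo.DesignMatrix(study_data.factors, study_data.points[:10])
        with pytest.raises(SingularDesignError):
            xo.fit_quadratic(short)

    def test_matches_statsmodels(self, study_data, full_fit):
        """Independent OLS cross-check."""
        sm = pytest.importorskip("statsmodels.api")
        model, _ = full_fit
        X = xo.expand_quadratic(study_data.coded)
        res = sm.OLS(study_data.responses, X).fit()
        assert np.allclose(model.coefficients, res.params, atol=1e-8)


class TestAnova:
    def test_reproduces_published_summary(self, full_fit):
        _, table = full_fit
        assert round(table.row("Model")["F"], 2) == 18.96
        assert round(table.r_squared, 4) == 0.9465
        assert round(table.adj_r_squared, 4) == 0.8966

    def test_reproduces_published_term_rows(self, full_fit):
        _, table = full_fit
        assert round(table.row("x1")["ss"], 2) == 3410.55
        assert round(table.row("x3:x4")["ss"], 2) == 3180.40
        assert round(table.row("x2^2")["ss"], 2) == 2572.45
        assert table.row("x2")["p"] > 0.05

    def test_lack_of_fit_split(self, full_fit):
        _, table = full_fit
        assert round(table.row("Lack of Fit")["F"], 2) == 33.23
        assert table.row("Lack of Fit")["df"] == 10
        assert table.row("Pure Error")["df"] == 5

    def test_sum_of_squares_conservation(self, study_data, full_fit):
        _, table = full_fit
        y = study_data.responses
        ss_total = ((y - y.mean()) ** 2).sum()
        assert table.row("Model")["ss"] + table.row("Residual")["ss"] == pytest.approx(
            ss_total
        )
        assert table.row("Lack of Fit")["ss"] + table.row("Pure Error")[
            "ss"
        ] == pytest.approx(table.row("Residual")["ss"])

    def test_degrees_of_freedom_sum(self, full_fit):
        _, table = full_fit
        assert table.row("Model")["df"] + table.row("Residual")["df"] == 29

    def test_partial_ss_equals_coefficient_form(self, study_data, full_fit):
        """For orthogonal columns, SS(term) = coef^2 * sum(column^2)."""
        model, table = full_fit
        X = xo.expand_quadratic(study_data.coded)
        named = dict(zip(TERM_NAMES, model.coefficients))
        for idx, name in enumerate(TERM_NAMES):
            if name == "intercept" or "^" in name:
                continue
            expected = named[name] ** 2 * (X[:, idx] ** 2).sum()
            assert table.row(name)["ss"] == pytest.approx(expected, rel=1e-9)

    def test_noiseless_fit_is_perfect(self, study_factors, rng):
        truth = xo.QuadraticModel(rng.normal(0, 5, 15))
        truth.coefficients[0] = 350.0
        design = xo.build_ccd(study_factors)
        design = design.with_responses(truth.predict(design.coded))
        model = xo.fit_quadratic(design)
        table = xo.anova(model, design)
        assert table.row("Residual")["ss"] == pytest.approx(0.0, abs=1e-12)
        assert table.r_squared == pytest.approx(1.0)

    def test_lack_of_fit_absent_without_replicates(self, study_factors, rng):
        design = xo.build_ccd(study_factors, n_center=1)
        design = design.with_responses(
            400 + rng.normal(0, 5, len(design)) + design.coded[:, 0]
        )
        table = xo.anova(xo.fit_quadratic(design), design)
        assert not table.has_lack_of_fit
        assert "Lack of Fit" not in table.table.index

    def test_matches_statsmodels_f_and_p(self, study_data, full_fit):
        sm = pytest.importorskip("statsmodels.api")
        _, table = full_fit
        X = xo.expand_quadratic(study_data.coded)
        res = sm.OLS(study_data.responses, X).fit()
        assert table.row("Model")["F"] == pytest.approx(res.fvalue)
        assert table.r_squared == pytest.approx(res.rsquared)
        assert table.adj_r_squared == pytest.approx(res.rsquared_adj)


class TestPredictedRSquared:
    def test_reproduces_published_value(self, study_data, full_fit):
        model, table = full_fit
        assert round(xo.predicted_r_squared(model, study_data), 4) == 0.6954
        assert round(table.pred_r_squared, 4) == 0.6954

    def test_press_identity_vs_brute_force_refits(self, study_data, full_fit):
        """The hat-matrix PRESS shortcut must equal literal leave-one-out refits."""
        model, _ = full_fit
        y = study_data.responses
        press = 0.0
        for i in range(len(study_data)):
            keep = [j for j in range(len(study_data)) if j != i]
            sub = xo.DesignMatrix(study_data.factors, [study_data.points[j] for j in keep])
            refit = xo.fit_quadratic(sub)
            press += (y[i] - refit.predict(study_data.coded[i])) ** 2
        ss_total = ((y - y.mean()) ** 2).sum()
        assert xo.predicted_r_squared(model, study_data) == pytest.approx(
            1.0 - press / ss_total, abs=1e-10
        )

    def test_perfect_fit(self, study_factors, rng):
        truth = xo.QuadraticModel(rng.normal(0, 2, 15))
        design = xo.build_ccd(study_factors)
        design = design.with_responses(truth.predict(design.coded) + 300)
        model = xo.fit_quadratic(design)
        assert xo.predicted_r_squared(model, design) == pytest.approx(1.0)

    def test_never_exceeds_r_squared(self, study_data, full_fit, pruned_model):
        _, table = full_fit
        assert table.pred_r_squared <= table.r_squared
        assert table.adj_r_squared <= table.r_squared
        pruned_anova = xo.anova(pruned_model, study_data)
        assert pruned_anova.pred_r_squared <= pruned_anova.r_squared


class TestAdequatePrecision:
    def test_reproduces_published_value(self, study_data, full_fit):
        model, _ = full_fit
        assert round(xo.adequate_precision(model, study_data), 3) == 15.413

    def test_constant_response_gives_zero(self, study_factors):
        design = xo.build_ccd(study_factors)
        design = design.with_responses([350.0] * len(design))
        model = xo.fit_quadratic(design)
        assert xo.adequate_precision(model, design) == 0.0

    def test_scale_invariance(self, study_data, full_fit):
        """Doubling all responses doubles signal and noise alike."""
        model, _ = full_fit
        doubled = study_data.with_responses(study_data.responses * 2)
        model2 = xo.fit_quadratic(doubled)
        assert xo.adequate_precision(model2, doubled) == pytest.approx(
            xo.adequate_precision(model, study_data)
        )


class TestPruning:
    def test_active_set_matches_published_equation(self, pruned_model):
        assert set(pruned_model.active_terms) == {
            "intercept", "x1", "x3", "x4", "x3:x4", "x1^2", "x2^2",
        }

    def test_alpha_one_keeps_everything(self, study_data, full_fit):
        model, table = full_fit
        kept = xo.prune_nonsignificant(model, table, alpha=1.0)
        assert kept.n_active == 15

    def test_truncation_keeps_full_model_estimates(self, full_fit, pruned_model):
        model, _ = full_fit
        assert np.array_equal(
            pruned_model.coefficients[pruned_model.term_active],
            model.coefficients[pruned_model.term_active],
        )

    def test_refit_mode_changes_only_nonorthogonal_terms(self, study_data, full_fit):
        model, table = full_fit
        refitted = xo.prune_nonsignificant(
            model, table, refit=True, design=study_data
        )
        named_full = dict(zip(TERM_NAMES, model.coefficients))
        named_refit = dict(zip(TERM_NAMES, refitted.coefficients))
        # linear and interaction columns are orthogonal: estimates unchanged
        for name in ("x1", "x3", "x4", "x3:x4"):
            assert named_refit[name] == pytest.approx(named_full[name], abs=1e-9)


class TestPredict:
    def test_intercept_at_center(self, reduced_surface):
        assert reduced_surface.predict(np.zeros(4)) == pytest.approx(365.45)

    def test_published_optimum_value(self, reduced_surface):
        value = reduced_surface.predict(np.array([0.722, 0.0, 2.0, -2.0]))
        assert round(value, 3) == 427.156

    def test_hand_arithmetic_point(self, reduced_surface):
        value = reduced_surface.predict(np.array([1.0, 1.0, -1.0, 1.0]))
        assert value == pytest.approx(373.04)

    def test_serialization_roundtrip(self, pruned_model, tmp_path):
        path = tmp_path / "model.json"
        pruned_model.to_json(path)
        again = xo.QuadraticModel.from_json(path)
        assert np.array_equal(again.coefficients, pruned_model.coefficients)
        assert np.array_equal(again.term_active, pruned_model.term_active)


def test_parameter_recovery_within_standard_errors(study_factors):
    """Simulated CCD data from known coefficients: every fitted coefficient
    lies within 4 proper standard errors of truth in >=95% of replicates."""
    truth = xo.QuadraticModel.from_named_coefficients(xo.STUDY_SURFACE)
    coefs_true = np.where(truth.term_active, truth.coefficients, 0.0)
    design = xo.build_ccd(study_factors)
    X = xo.expand_quadratic(design.coded)
    sigma = xo.STUDY_NOISE_SD
    cov_unit = np.linalg.inv(X.T @ X)
    se = sigma * np.sqrt(np.diag(cov_unit))
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        data, _ = xo.generate_quadratic_dataset(
            xo.SyntheticSpec(true_coefficients=truth, noise_sd=sigma, seed=rep),
            study_factors,
        )
        fitted = xo.fit_quadratic(data)
        if np.all(np.abs(fitted.coefficients - coefs_true) <= 4 * se):
            hits += 1
    assert hits / n_rep >= 0.95
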