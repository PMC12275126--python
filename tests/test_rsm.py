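import numpy as np
import pytest
import statsmodels.api as sm

import extractopt as eo
from extractopt.errors import SingularDesignError
from extractopt.rsm import TERM_NAMES, quadratic_design_matrix
from extractopt.synthetic import SurfaceSpec, simulate_table

from conftest import make_true_model


class TestFitQuadratic:
    def test_recovers_noiseless_coefficients(self):
        true = make_true_model(coding="coded")
        table = simulate_table(SurfaceSpec(true, noise_sd=0.0), seed=7)
        fit = eo.fit_quadratic(table, coding="coded")
        assert fit.intercept == pytest.approx(true.intercept, rel=1e-8)
        assert np.allclose(fit.coefficients, true.coefficients, rtol=1e-8, atol=1e-10)

    def test_fixture_goodness_of_fit(self, fixture_table, fixture_model):
        resid = fixture_table.yields - fixture_model.fitted
        sst = ((fixture_table.yields - fixture_table.yields.mean()) ** 2).sum()
        r2 = 1 - (resid @ resid) / sst
        rmse = np.sqrt((resid @ resid) / 29)
        assert r2 == pytest.approx(0.896, abs=0.02)
        assert rmse == pytest.approx(0.8852, rel=0.02)

    def test_fitted_surface_reproduces_printed_predictions(self, fixture_table,
                                                           fixture_model):
        """The printed response-surface prediction column is the OLS fitted
        values of the quadratic refit, to the 2-decimal printing."""
        assert np.allclose(np.round(fixture_model.fitted, 2),
                           fixture_table.aux_column("pred_rsm"), atol=0.011)

    def test_coded_and_actual_codings_agree(self, fixture_table):
        coded = eo.fit_quadratic(fixture_table, coding="coded")
        actual = eo.fit_quadratic(fixture_table, coding="actual")
        assert np.max(np.abs(coded.fitted - actual.fitted)) < 1e-8
        pts = fixture_table.factors[:7] + 1.3
        assert np.allclose(coded.predict(pts), actual.predict(pts), rtol=1e-8)

    def test_rank_deficient_design_rejected(self, fixture_table):
        frame = fixture_table.frame
        degenerate = eo.DesignTable(frame.assign(power_w=300.0),
                                    domains=fixture_table.domains)
        with pytest.raises(SingularDesignError):
            eo.fit_quadratic(degenerate)


class TestPredict:
    def test_intercept_only_is_constant(self):
        m = eo.QuadraticModel(4.2, np.zeros(14), "actual", eo.PAPER_DOMAINS)
        pts = np.array([[20, 80, 60, 250], [30, 100, 90, 350]], float)
        assert np.allclose(m.predict(pts), 4.2)

    def test_pure_interaction_term(self):
        coefs = np.zeros(14)
        coefs[TERM_NAMES.index("AB")] = 1.0
        m = eo.QuadraticModel(0.0, coefs, "actual", eo.PAPER_DOMAINS)
        assert m.predict(np.array([2.0, 3.0, 0.0, 0.0])) == pytest.approx(6.0)

    def test_center_replicates_share_one_prediction(self, fixture_table, fixture_model):
        center = fixture_table.factors[fixture_table.center_mask()]
        preds = fixture_model.predict(center)
        assert np.ptp(preds) < 1e-10
        fitted_centers = fixture_model.fitted[fixture_table.center_mask()]
        assert preds[0] == pytest.approx(fitted_centers.mean())


class TestAnova:
    def test_fixture_f_statistics(self, fixture_anova):
        assert fixture_anova.row("Model").f == pytest.approx(8.62, rel=0.02)
        assert fixture_anova.row("Model").df == 14
        assert fixture_anova.row("B").f == pytest.approx(68.91, rel=0.02)

    def test_sum_of_squares_conservation(self, rng):
        true = make_true_model()
        table = simulate_table(SurfaceSpec(true, noise_sd=1.0), seed=11)
        rep = eo.anova(eo.fit_quadratic(table), table)
        ss_model = rep.row("Model").ss
        ss_res = rep.row("Residual").ss
        ss_tot = rep.row("Cor Total").ss
        assert ss_model + ss_res == pytest.approx(ss_tot, rel=1e-8)
        assert rep.row("Lack of Fit").ss + rep.row("Pure Error").ss == \
            pytest.approx(ss_res, rel=1e-8)
        assert rep.row("Model").df + rep.row("Residual").df == rep.row("Cor Total").df

    def test_type1_and_type3_agree_on_orthogonal_terms(self, fixture_model,
                                                       fixture_table):
        t3 = eo.anova(fixture_model, fixture_table, ss_method="type3")
        t1 = eo.anova(fixture_model, fixture_table, ss_method="type1")
        for term in ("A", "B", "C", "D", "AB", "AC", "AD", "BC", "BD", "CD"):
            assert t1.row(term).ss == pytest.approx(t3.row(term).ss, rel=1e-6)

    def test_no_replicates_means_lof_equals_residual(self):
        true = make_true_model()
        table = simulate_table(SurfaceSpec(true, noise_sd=0.5, n_center=1), seed=3)
        rep = eo.anova(eo.fit_quadratic(table), table)
        assert rep.row("Lack of Fit").ss == pytest.approx(rep.row("Residual").ss)
        with pytest.raises(KeyError):
            rep.row("Pure Error")

    def test_cv_definition(self, fixture_anova, fixture_table):
        ms_res = fixture_anova.row("Residual").ms
        expected = 100 * np.sqrt(ms_res) / fixture_table.yields.mean()
        assert fixture_anova.cv_pct == pytest.approx(expected)

    def test_small_p_rendered_as_inequality(self, fixture_anova):
        assert "< 0.0001" in fixture_anova.to_text()

    def test_interval_coverage_near_nominal(self):
        """95 % t-intervals on the quadratic coefficients cover the truth at
        roughly nominal rate across noisy replicated surfaces."""
        true = make_true_model()
        beta = np.concatenate([[true.intercept], true.coefficients])
        covered, total = 0, 0
        for rep in range(200):
            table = simulate_table(SurfaceSpec(true, noise_sd=1.27), seed=1000 + rep)
            M = quadratic_design_matrix(table.coded)
            ci = sm.OLS(table.yields, M).fit().conf_int(alpha=0.05)
            covered += int(((ci[:, 0] <= beta) & (beta <= ci[:, 1])).sum())
            total += len(beta)
        assert covered / total == pytest.approx(0.95, abs=0.03)


class TestPress:
    def test_hat_matrix_equals_explicit_refits(self, fixture_table, fixture_model):
        shortcut = eo.press(fixture_model, fixture_table)
        y = fixture_table.yields
        M = quadratic_design_matrix(fixture_table.coded)
        brute = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta = np.linalg.lstsq(M[keep], y[keep], rcond=None)[0]
            brute += (y[i] - M[i] @ beta) ** 2
        assert shortcut == pytest.approx(brute, rel=1e-10)

    def test_press_at_least_residual_ss(self, fixture_anova):
        assert fixture_anova.press >= fixture_anova.row("Residual").ss
        assert fixture_anova.pred_r2 <= fixture_anova.r2

    def test_constant_response_on_replicated_design_gives_zero(self):
        true = eo.QuadraticModel(12.0, np.zeros(14), "coded", eo.PAPER_DOMAINS)
        table = simulate_table(SurfaceSpec(true, noise_sd=0.0, n_center=5), seed=1)
        model = eo.fit_quadratic(table)
        assert eo.press(model, table) == pytest.approx(0.0, abs=1e-16)
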