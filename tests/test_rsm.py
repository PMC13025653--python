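"""Box-Behnken design, quadratic fitting, ANOVA and desirability tests.

The corn hydrolysis dataset bundled with the package serves as the
reference: its published regression equations and ANOVA tables pin down
the expected coefficients and statistics to print precision.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptriact import datasets, rsm
from peptriact.errors import DesignError, FitError

FACTORS = datasets.CORN_FACTORS


class TestDesignConstruction:
    def test_seventeen_run_design_matches_corn_table(self):
        generated = rsm.generate_bbd(FACTORS, n_center=5)
        expected = datasets.load_corn_design()
        got = sorted(map(tuple, np.round(generated.actual, 6)))
        want = sorted(map(tuple, np.round(expected.actual, 6)))
        assert got == want

    @pytest.mark.parametrize("n_center,total", [(1, 13), (3, 15), (5, 17)])
    def test_run_count(self, n_center, total):
        assert rsm.generate_bbd(FACTORS, n_center).n_runs == total

    def test_every_edge_run_has_exactly_one_center_coordinate(self):
        design = rsm.generate_bbd(FACTORS, 1)
        edges = design.coded[~design.center_mask]
        assert edges.shape == (12, 3)
        assert np.all((edges == 0).sum(axis=1) == 1)
        assert np.all(np.isin(edges[edges != 0], [-1.0, 1.0]))

    def test_linear_columns_orthogonal(self):
        X = rsm.model_matrix(rsm.generate_bbd(FACTORS, 5).coded)
        # linear columns mutually orthogonal and orthogonal to interactions
        for i in (1, 2, 3):
            for j in (1, 2, 3, 4, 5, 6):
                if i != j:
                    assert abs(X[:, i] @ X[:, j]) < 1e-12

    def test_non_three_factor_designs_rejected(self):
        with pytest.raises(DesignError):
            rsm.generate_bbd(FACTORS[:2], 5)

    def test_validate_bbd_rejects_mangled_design(self, corn_design):
        broken = rsm.DesignTable(
            corn_design.factors,
            np.vstack([corn_design.coded[:11], [[1.0, 1.0, 1.0]], corn_design.coded[12:]]),
            np.array([
                rsm.uncode_point(corn_design.factors, r)
                for r in np.vstack([corn_design.coded[:11], [[1, 1, 1]], corn_design.coded[12:]])
            ]),
        )
        with pytest.raises(DesignError):
            broken.validate_bbd()


class TestCoding:
    def test_center_maps_to_origin(self):
        assert rsm.code_point(FACTORS, (1.25, 2.25, 27.5)) == pytest.approx((0, 0, 0))

    def test_reported_optimum_coding(self):
        coded = rsm.code_point(FACTORS, (1.35, 2.30, 27.44))
        assert coded == pytest.approx((0.4, 0.0667, -0.008), abs=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(st.tuples(st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2)))
    def test_round_trip(self, coded):
        actual = rsm.uncode_point(FACTORS, coded)
        assert rsm.code_point(FACTORS, actual) == pytest.approx(coded, abs=1e-9)

    def test_asymmetric_center_warns(self):
        with pytest.warns(UserWarning, match="midpoint"):
            rsm.FactorSpec("x", 0.0, 0.4, 1.0)


class TestQuadraticFit:
    def test_corn_dh_equation(self, corn_fits):
        beta = corn_fits["DH"].coefficients
        assert round(beta[0], 2) == pytest.approx(46.21)
        assert round(beta[1], 2) == pytest.approx(2.12)  # enzyme dosage
        assert round(beta[2], 2) == pytest.approx(7.30)  # hydrolysis time
        assert round(beta[3], 2) == pytest.approx(6.26, abs=0.011)  # solid-liquid

    def test_corn_dpph_equation(self, corn_fits):
        beta = corn_fits["DPPH"].coefficients
        assert round(beta[0], 2) == pytest.approx(61.33)
        assert round(beta[7], 2) == pytest.approx(-25.36)

    def test_linear_coefficient_shortcut(self, corn_design, corn_fits):
        # on a 3-factor BBD each linear coefficient is (sum at +1 - sum at -1)/8
        for name, fit in corn_fits.items():
            y = corn_design.responses[name]
            for j in range(3):
                col = corn_design.coded[:, j]
                expected = (y[col == 1.0].sum() - y[col == -1.0].sum()) / 8.0
                assert fit.coefficients[1 + j] == pytest.approx(expected, rel=1e-9)

    def test_noiseless_surface_recovered_exactly(self):
        rng = np.random.default_rng(42)
        beta_true = rng.normal(0, 5, size=10)
        design = rsm.generate_bbd(FACTORS, 5)
        design.responses["Y"] = rsm.model_matrix(design.coded) @ beta_true
        fit = rsm.fit_quadratic(design, "Y")
        assert fit.coefficients == pytest.approx(beta_true, rel=1e-9, abs=1e-9)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_ols(self, corn_design, corn_fits):
        statsmodels = pytest.importorskip("statsmodels.api")
        X = rsm.model_matrix(corn_design.coded)
        for name, fit in corn_fits.items():
            res = statsmodels.OLS(corn_design.responses[name], X).fit()
            assert fit.coefficients == pytest.approx(res.params, rel=1e-9)
            assert fit.residual_ss == pytest.approx(res.ssr, rel=1e-9)

    def test_missing_response_rejected(self, corn_design):
        with pytest.raises(FitError):
            rsm.fit_quadratic(corn_design, "nope")


class TestAnova:
    def test_corn_dh_table(self, corn_design, corn_fits):
        rep = rsm.anova(corn_fits["DH"], corn_design)
        model = rep.row("Model")
        assert model["F"] == pytest.approx(33.73, abs=0.005)
        assert model["SS"] == pytest.approx(1053.40, abs=0.005)
        assert rep.row("Lack of fit")["F"] == pytest.approx(1.92, abs=0.005)
        assert rep.r2 == pytest.approx(0.9775, abs=5e-5)
        assert rep.r2_adj == pytest.approx(0.9485, abs=5e-5)
        assert rep.cv_percent == pytest.approx(4.22, abs=0.005)

    def test_corn_dpph_quadratic_term(self, corn_design, corn_fits):
        rep = rsm.anova(corn_fits["DPPH"], corn_design)
        row = rep.row("A^2")
        assert row["SS"] == pytest.approx(2707.86, abs=0.01)
        assert row["F"] == pytest.approx(131.91, abs=0.01)

    def test_corn_adh_cv(self, corn_design, corn_fits):
        rep = rsm.anova(corn_fits["ADH"], corn_design)
        assert rep.cv_percent == pytest.approx(22.06, abs=0.005)

    def test_decomposition_identities(self, corn_design, corn_fits):
        for fit in corn_fits.values():
            rep = rsm.anova(fit, corn_design)
            model, resid = rep.row("Model"), rep.row("Residual")
            total = rep.row("Cor total")
            lof, pe = rep.row("Lack of fit"), rep.row("Pure error")
            assert model["SS"] + resid["SS"] == pytest.approx(total["SS"], rel=1e-9)
            assert lof["SS"] + pe["SS"] == pytest.approx(resid["SS"], rel=1e-9)
            assert model["Df"] + resid["Df"] == total["Df"]
            assert lof["Df"] + pe["Df"] == resid["Df"]
            assert rep.r2 == pytest.approx(model["SS"] / total["SS"], rel=1e-12)

    def test_corn_dh_decomposition_to_print_precision(self, corn_design, corn_fits):
        rep = rsm.anova(corn_fits["DH"], corn_design)
        assert round(rep.row("Model")["SS"], 2) + round(rep.row("Residual")["SS"], 2) == pytest.approx(1077.69)
        assert round(rep.row("Lack of fit")["SS"], 2) == pytest.approx(14.33)
        assert round(rep.row("Pure error")["SS"], 2) == pytest.approx(9.96)

    def test_linear_partial_ss_equals_8_coef_squared(self, corn_design, corn_fits):
        for name, fit in corn_fits.items():
            rep = rsm.anova(fit, corn_design)
            for j, term in enumerate(("A", "B", "C"), start=1):
                assert rep.row(term)["SS"] == pytest.approx(
                    8.0 * fit.coefficients[j] ** 2, rel=1e-9
                )

    def test_quadratic_term_ss_not_additive(self, corn_design, corn_fits):
        # partial (drop-one) SS: quadratic columns are non-orthogonal, so
        # per-term SS do not sum to the model SS -- expected, not a bug
        rep = rsm.anova(corn_fits["DH"], corn_design)
        term_sum = sum(rep.row(t)["SS"] for t in rsm.TERM_NAMES[1:])
        assert abs(term_sum - rep.row("Model")["SS"]) > 1.0

    def test_no_replicates_warns_and_skips_lof(self):
        design = rsm.generate_bbd(FACTORS, 1)
        rng = np.random.default_rng(0)
        design.responses["Y"] = rng.normal(50, 5, design.n_runs)
        fit = rsm.fit_quadratic(design, "Y")
        with pytest.warns(UserWarning, match="replicate"):
            rep = rsm.anova(fit, design)
        assert not rep.has_lof
        assert "Lack of fit" not in set(rep.table["Source"])

    def test_pure_noise_response_yields_modest_r2_and_uniform_p(self):
        # zero surface: the model p-value should be ~Uniform(0,1) across seeds
        design = rsm.generate_bbd(FACTORS, 5)
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            design.responses["Y"] = rng.normal(0.0, 1.0, design.n_runs)
            fit = rsm.fit_quadratic(design, "Y")
            rep = rsm.anova(fit, design)
            pvals.append(rep.row("Model")["p"])
        pvals = np.array(pvals)
        assert 0.35 < pvals.mean() < 0.65
        assert (pvals < 0.05).mean() < 0.12


class TestPredict:
    def test_center_returns_intercept(self, corn_fits):
        for fit in corn_fits.values():
            assert rsm.predict(fit, (0, 0, 0)) == pytest.approx(fit.coefficients[0], rel=1e-12)

    def test_corn_predictions_at_reported_optimum(self, corn_fits):
        point = rsm.code_point(FACTORS, datasets.CORN_OPTIMUM_ACTUAL)
        assert rsm.predict(corn_fits["DH"], point) == pytest.approx(48.00, abs=0.15)
        assert rsm.predict(corn_fits["ADH"], point) == pytest.approx(12.92, abs=0.15)
        assert rsm.predict(corn_fits["DPPH"], point) == pytest.approx(55.79, abs=0.25)

    def test_zero_coefficients_predict_zero(self):
        fit = rsm.QuadraticFit("Z", np.zeros(10), 0.0, 0.0, 0.0, 17, 0.0, 1.0)
        assert rsm.predict(fit, (0.3, -0.7, 1.0)) == 0.0


class TestDesirability:
    def _single_concave_fit(self):
        # Y = 10 - (a-0.3)^2 - (b+0.2)^2 - c^2, expanded into the 10-term basis
        beta = np.array([10 - 0.09 - 0.04, 0.6, -0.4, 0.0, 0, 0, 0, -1.0, -1.0, -1.0])
        return rsm.QuadraticFit("Y", beta, 0.0, 1.0, 9.0, 17, 0.0, 9.0)

    def test_single_concave_quadratic_argmax(self):
        fit = self._single_concave_fit()
        goals = {"Y": rsm.DesirabilityGoal(low=0.0, high=11.0)}  # keep the ramp unclipped
        res = rsm.optimize_desirability([fit], FACTORS, goals)
        assert res.point_coded == pytest.approx((0.3, -0.2, 0.0), abs=1e-4)

    def test_argmax_invariant_to_common_weight_rescaling(self, corn_fits):
        fits = list(corn_fits.values())
        base = rsm.optimize_desirability(fits, FACTORS)
        doubled = rsm.optimize_desirability(
            fits, FACTORS,
            {f.response_name: rsm.DesirabilityGoal(weight=2.0) for f in fits},
        )
        assert doubled.point_coded == pytest.approx(base.point_coded, abs=1e-5)
        assert doubled.desirability == pytest.approx(base.desirability, rel=1e-6)

    def test_result_is_consistent_and_inside_cube(self, corn_fits):
        res = rsm.optimize_desirability(list(corn_fits.values()), FACTORS)
        assert all(-1.0 <= v <= 1.0 for v in res.point_coded)
        assert 0.0 <= res.desirability <= 1.0
        for name, fit in corn_fits.items():
            assert res.predicted_responses[name] == pytest.approx(
                rsm.predict(fit, res.point_coded), rel=1e-12
            )
        assert res.point_actual == pytest.approx(
            rsm.uncode_point(FACTORS, res.point_coded)
        )

    def test_empty_fits_rejected(self):
        with pytest.raises(Exception):
            rsm.optimize_desirability([], FACTORS)
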