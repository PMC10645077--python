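"""Growth-rate model family: prediction, fitting, AICc and model selection."""

import numpy as np
import pytest

from paleodyn.errors import CollinearityError, ComparisonError, ValidationError
from paleodyn.models import (
    MODEL_SPECS,
    ModelSpec,
    ParameterSet,
    PopulationDynamicsModel,
    aicc,
    fit_all_models,
    fit_model,
    model_selection,
    predict_growth_rate,
)

from conftest import random_table


class TestPredictGrowthRate:
    def test_reduces_to_intercept(self):
        assert predict_growth_rate(ParameterSet(R_m=0.7), X=1.3) == pytest.approx(0.7)

    def test_endogenous_value(self):
        p = ParameterSet(R_m=1.0, c=10.0, w=0.05)
        # R = 1 - 10*0.1 - 0.05*10 = -0.5
        assert predict_growth_rate(p, X=np.log(0.1)) == pytest.approx(-0.5)

    def test_covariate_coupling_value(self):
        p = ParameterSet(alpha0=2.0)
        assert predict_growth_rate(p, X=0.0, z=0.5) == pytest.approx(-1.0)

    def test_vectorised(self):
        p = ParameterSet(R_m=0.3, c=0.01, w=0.2)
        X = np.array([0.0, 1.0, 2.0])
        out = predict_growth_rate(p, X)
        expected = 0.3 - 0.01 * np.exp(X) - 0.2 * np.exp(-X)
        np.testing.assert_allclose(out, expected)


class TestFitModel:
    def test_exact_recovery_noise_free(self, table_from_model_a):
        params, table = table_from_model_a
        fit = fit_model("A", table)
        assert fit.params.R_m == pytest.approx(params.R_m, abs=1e-8)
        assert fit.params.c == pytest.approx(params.c, abs=1e-8)
        assert fit.params.w == pytest.approx(params.w, abs=1e-8)
        assert fit.rss < 1e-16

    @pytest.mark.parametrize("spec_name", list(MODEL_SPECS))
    def test_matches_normal_equations_oracle(self, spec_name):
        for seed in range(10):
            table = random_table(seed)
            model = PopulationDynamicsModel(table, spec_name)
            fit = model.fit()
            XtX = model.exog.T @ model.exog
            beta = np.linalg.solve(XtX, model.exog.T @ model.endog)
            np.testing.assert_allclose(fit.params_array, beta, atol=1e-10)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        table = random_table(42)
        model = PopulationDynamicsModel(table, "D")
        fit = model.fit()
        ref = sm.OLS(model.endog, model.exog).fit()
        np.testing.assert_allclose(fit.params_array, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.rss, ref.ssr, rtol=1e-10)

    def test_nls_mode_equals_ols(self):
        table = random_table(7)
        ols = fit_model("D", table, method="ols")
        nls = fit_model("D", table, method="nls")
        np.testing.assert_allclose(nls.params_array, ols.params_array, atol=1e-6)

    def test_nested_rss_monotone(self):
        for seed in range(20):
            table = random_table(seed)
            rss = {name: fit_model(name, table).rss for name in "ABCD"}
            assert rss["D"] <= rss["C"] + 1e-12
            assert rss["C"] <= rss["B"] + 1e-12
            assert rss["B"] <= rss["A"] + 1e-12

    def test_collinear_regressors_named(self):
        table = random_table(0)
        df = table.frame.copy()
        df["z_warfare"] = df["z_lithic"]  # duplicates the alpha1 column
        from paleodyn.proxies import GenerationTable

        with pytest.raises(CollinearityError, match="alpha1"):
            PopulationDynamicsModel(GenerationTable(frame=df), "B").fit()

    def test_too_few_rows(self):
        table = random_table(0, n=5)
        with pytest.raises(ValidationError, match="needs"):
            PopulationDynamicsModel(table, "D")

    def test_summary_mentions_params(self):
        fit = fit_model("D", random_table(1))
        text = fit.summary()
        for name in ("R_m", "alpha0", "beta1", "AICc"):
            assert name in text


class TestAICc:
    def test_direct_formula_value(self):
        # n*[ln(2*pi*rss/n)+1] + 2K + 2K(K+1)/(n-K-1), K = 4
        assert aicc(0.1, 54, 3) == pytest.approx(-177.68, abs=0.01)

    def test_equal_inputs_equal_output(self):
        assert aicc(0.37, 54, 5) == aicc(0.37, 54, 5)

    def test_penalty_strictly_increasing_in_params(self):
        vals = [aicc(0.1, 54, k) for k in range(1, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_undefined_correction(self):
        with pytest.raises(ValidationError, match="undefined"):
            aicc(0.1, 6, 5)


class TestModelSelection:
    def test_published_style_aicc_set(self):
        """AICc set {-96.06, -92.34, -92.43, -109.61}: the endogenous model
        sits 13.55 above the best and the weights round to (0,0,0,1)."""
        targets = {"A": -96.06, "B": -92.34, "C": -92.43, "D": -109.61}

        class Stub:
            def __init__(self, name, val, n=54):
                self.spec = MODEL_SPECS[name]
                self.n = n
                self.n_params = self.spec.n_params
                self.aicc = val
                self.delta_aicc = None
                self.akaike_weight = None

        comp = model_selection([Stub(k, v) for k, v in targets.items()])
        by_name = {f.spec.name: f for f in comp.fits}
        assert by_name["A"].delta_aicc == pytest.approx(13.55, abs=0.01)
        assert round(by_name["D"].akaike_weight, 2) == 1.0
        for name in "ABC":
            assert round(by_name[name].akaike_weight, 2) == 0.0

    def test_equal_aicc_equal_weights(self):
        class Stub:
            def __init__(self, name):
                self.spec = MODEL_SPECS[name]
                self.n = 54
                self.n_params = self.spec.n_params
                self.aicc = -100.0
                self.delta_aicc = None
                self.akaike_weight = None

        comp = model_selection([Stub("A"), Stub("B")])
        np.testing.assert_allclose(comp.akaike_weights, [0.5, 0.5])
        # ties rank by fewer parameters: A first
        assert comp.best.spec.name == "A"

    def test_weights_sum_to_one_and_shift_invariant(self):
        table = random_table(11)
        comp = fit_all_models(table)
        assert comp.akaike_weights.sum() == pytest.approx(1.0, abs=1e-9)

        class Shifted:
            def __init__(self, f, shift):
                self.spec = f.spec
                self.n = f.n
                self.n_params = f.n_params
                self.aicc = f.aicc + shift
                self.delta_aicc = None
                self.akaike_weight = None

        shifted = model_selection([Shifted(f, 123.4) for f in comp.fits])
        np.testing.assert_allclose(shifted.akaike_weights, comp.akaike_weights,
                                   atol=1e-12)

    def test_relative_importance_follows_weights(self):
        table = random_table(5)
        comp = fit_all_models(table)
        imp = comp.relative_importance()
        w = {f.spec.name: f.akaike_weight for f in comp.fits}
        # lithic enters B, C, D; pollution C, D; warfare B, C, D
        assert imp["lithic"] == pytest.approx(w["B"] + w["C"] + w["D"], abs=1e-12)
        assert imp["pollution"] == pytest.approx(w["C"] + w["D"], abs=1e-12)
        assert 0.0 <= min(imp.values()) and max(imp.values()) <= 1.0 + 1e-12

    def test_mixed_tables_rejected(self):
        f1 = fit_model("A", random_table(0, n=55))
        f2 = fit_model("B", random_table(1, n=40))
        with pytest.raises(ComparisonError, match="different n"):
            model_selection([f1, f2])

    def test_spec_definitions_follow_nesting(self):
        assert MODEL_SPECS["A"].n_params == 3
        assert MODEL_SPECS["B"].n_params == 5
        assert MODEL_SPECS["C"].n_params == 6
        assert MODEL_SPECS["D"].n_params == 7
        with pytest.raises(ValidationError):
            ModelSpec("X", covariates_on_c=("pollution",))
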