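"""MaxEnt core: features, fitting, AICc, tuning, diagnostics.

The fitting tests check the model against independent oracles: closed-form
limits (penalty-dominated, single-feature sign) and a direct numeric
minimization of an independently coded objective on tiny instances.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import enmkit as ek
from enmkit.errors import ConfigError
from enmkit.features import build_features


@pytest.fixture(scope="module")
def tiny_instance():
    rng = np.random.default_rng(5)
    bg = pd.DataFrame({"v": rng.uniform(0, 10, size=40)})
    occ = pd.DataFrame({"v": rng.uniform(7, 10, size=12)})
    return occ, bg


class TestBuildFeatures:
    def test_feature_counts_by_class(self):
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        assert len(build_features(bg, fc="L")) == 5
        assert len(build_features(bg, fc="LQ")) == 10
        assert len(build_features(bg, fc="LQP")) == 10 + 10  # C(5,2) products
        one = bg[["a"]]
        assert len(build_features(one, fc="LQH", hinge_knots=10)) == 1 + 1 + 20

    def test_features_scaled_into_unit_interval(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"a": rng.normal(10, 3, 200), "b": rng.uniform(0, 1, 200)})
        fs = build_features(bg, fc="LQHPT", hinge_knots=8)
        X = fs.transform(bg)
        assert X.min() >= 0.0 and X.max() <= 1.0
        # linear feature hits exactly 0 at the background min and 1 at the max
        lin = X[:, 0]
        assert lin[bg["a"].idxmin()] == 0.0 and lin[bg["a"].idxmax()] == 1.0

    def test_categorical_always_indicator(self):
        bg = pd.DataFrame({"a": np.linspace(0, 1, 30),
                           "lu": np.repeat([1.0, 2.0, 3.0], 10)})
        fs = build_features(bg, fc="LQHPT", hinge_knots=5, categorical=("lu",))
        kinds = fs.kinds()
        assert (kinds == "categorical").sum() == 3
        # land-use levels never enter quadratic/product/hinge expansions
        for d in fs.defs:
            if "lu" in d.variables:
                assert d.kind == "categorical"

    def test_too_few_hinge_knots_rejected(self):
        bg = pd.DataFrame({"a": np.linspace(0, 1, 30)})
        with pytest.raises(ConfigError):
            build_features(bg, fc="H", hinge_knots=1)


class TestFitMaxent:
    def test_huge_penalty_gives_null_model(self, tiny_instance):
        occ, bg = tiny_instance
        model = ek.fit_maxent(occ, bg, rm=1e6, fc="LQ")
        assert model.k == 0
        raw = model.predict_env(bg, output="raw")
        np.testing.assert_allclose(raw, 1.0 / model.n_background)

    def test_concentrated_occurrences_get_positive_coefficient(self, tiny_instance):
        occ, bg = tiny_instance
        model = ek.fit_maxent(occ, bg, rm=1.0, fc="L")
        assert model.beta[0] > 0

    def test_objective_matches_numeric_oracle_at_zero_penalty(self, tiny_instance):
        occ, bg = tiny_instance
        model = ek.fit_maxent(occ, bg, rm=0.0, fc="LQ")
        # independent objective: manual scaling, manual L+Q features,
        # derivative-free minimization
        lo, hi = bg["v"].min(), bg["v"].max()
        z_occ = np.clip((occ["v"].to_numpy() - lo) / (hi - lo), 0, 1)
        z_bg = np.clip((bg["v"].to_numpy() - lo) / (hi - lo), 0, 1)
        X_occ = np.column_stack([z_occ, z_occ ** 2])
        X_aug = np.vstack([np.column_stack([z_bg, z_bg ** 2]), X_occ])

        def objective(beta):
            return logsumexp(X_aug @ beta) - X_occ.mean(axis=0) @ beta

        res = minimize(objective, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert model.objective == pytest.approx(res.fun, abs=1e-4)

    def test_raw_density_normalized_over_background(self, tiny_instance):
        occ, bg = tiny_instance
        model = ek.fit_maxent(occ, bg, rm=0.5, fc="LQH", hinge_knots=5)
        total = (model.predict_env(bg, output="raw").sum()
                 + model.predict_env(occ, output="raw").sum())
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_sparsity_monotone_in_regularization(self, recovery_study):
        occ = recovery_study["occ_env"].head(200)
        bg = recovery_study["bg_env"].head(1000)
        cols = ["bio16", "bio15", "bio3"]
        ks = [ek.fit_maxent(occ[cols], bg[cols], rm=rm, fc="LQH", hinge_knots=8).k
              for rm in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_cloglog_preserves_raw_ranking(self, tiny_instance):
        occ, bg = tiny_instance
        model = ek.fit_maxent(occ, bg, rm=1.0, fc="LQ")
        raw = model.predict_env(bg, output="raw")
        clog = model.predict_env(bg, output="cloglog")
        assert (clog >= 0).all() and (clog <= 1).all()
        assert ek.auc(model.predict_env(occ, "raw"), raw) == pytest.approx(
            ek.auc(model.predict_env(occ, "cloglog"), clog))


class TestAicc:
    def test_closed_form_value(self):
        # -2(-10) + 2*3 + 2*3*4/(20-3-1) = 26 + 1.5
        assert ek.aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_zero_parameters(self):
        assert ek.aicc(-10.0, 0, 20) == pytest.approx(20.0)

    def test_overparameterized_candidate_disqualified(self):
        assert np.isinf(ek.aicc(-10.0, 19, 20))


@pytest.fixture(scope="module")
def small_tune(recovery_study):
    occ = recovery_study["occ_env"].head(60)
    bg = recovery_study["bg_env"].head(400)
    cols = ["bio16", "bio9"]
    return ek.tune_grid(occ[cols], bg[cols], k_folds=2, seed=1, hinge_knots=4)


class TestTuneGrid:

    def test_default_grid_enumerates_48_candidates(self, small_tune):
        table = small_tune.table
        assert len(table) == 8 * 6
        assert set(table["rm"]) == {0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0}
        assert set(table["fc"]) == {"L", "LQ", "H", "LQH", "LQHP", "LQHPT"}
        assert ((table["fc"] == "LQH") & (table["rm"] == 0.5)).any()

    def test_exactly_one_selected_row_within_aicc_window(self, small_tune):
        table = small_tune.table
        assert table["selected"].sum() == 1
        sel = table[table["selected"]].iloc[0]
        assert sel["aicc"] <= table["aicc"].min() + 2.0

    def test_selected_close_to_best_test_auc(self, recovery_study):
        table = recovery_study["tune"].table
        sel = recovery_study["tune"].selected
        assert sel["auc_test"] >= table["auc_test"].max() - 0.05


class TestDiagnostics:
    def test_importance_columns_sum_to_100(self, recovery_study):
        imp = recovery_study["importance"]
        assert imp["contribution"].sum() == pytest.approx(100.0, abs=0.1)
        assert imp["permutation_importance"].sum() == pytest.approx(100.0, abs=0.1)
        assert (imp["contribution"] >= 0).all()

    def test_single_variable_model_gets_everything(self, recovery_study):
        occ = recovery_study["occ_env"].head(150)
        bg = recovery_study["bg_env"].head(800)
        model = ek.fit_maxent(occ[["bio16"]], bg[["bio16"]], rm=1.0, fc="LQ")
        imp = ek.variable_importance(model, occ[["bio16"]], bg[["bio16"]], seed=0)
        assert imp["contribution"].iloc[0] == pytest.approx(100.0)
        assert imp["permutation_importance"].iloc[0] == pytest.approx(100.0)

    def test_jackknife_separates_driver_from_noise(self, recovery_study):
        occ = recovery_study["occ_env"].head(500)
        bg = recovery_study["bg_env"].head(2000)
        jk = ek.jackknife_gains(occ[["bio16", "bio9"]], bg[["bio16", "bio9"]],
                                rm=1.0, fc="LQH", hinge_knots=8)
        gains = jk.set_index("variable")["gain_with_only"]
        assert gains["bio16"] > gains["bio9"]
        assert abs(gains["bio9"]) < 0.05  # pure noise carries ~no gain

    def test_response_curve_flat_for_null_model(self, tiny_instance):
        occ, bg = tiny_instance
        model = ek.fit_maxent(occ, bg, rm=1e6, fc="LQ")
        curve = ek.response_curve(model, "v", n_points=50)
        assert len(curve) == 50
        assert curve["suitability"].nunique() == 1

    def test_response_curve_spans_background_range(self, recovery_study):
        curve = recovery_study["curve"]
        model = recovery_study["model"]
        assert curve["value"].iloc[0] == model.features.var_min["bio16"]
        assert curve["value"].iloc[-1] == model.features.var_max["bio16"]
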