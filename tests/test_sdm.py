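import numpy as np
import pandas as pd
import pytest

from fritniche.metrics import auc_score
from fritniche.occurrences import OccurrenceSet
from fritniche.raster import RasterGrid, RasterStack
from fritniche.sdm import (
    Ensemble,
    EnsembleSDM,
    LogisticIRLS,
    ResponseCurve,
    area_stats,
    build_ensemble,
    classify_habitat,
    cross_validate,
    fit_logistic,
    fit_sre,
    predict_raster,
    response_curve,
    sample_pseudo_absences,
    suitable_range,
    variable_importance,
)


class TestSRE:
    def test_q_zero_gives_min_max_envelope(self):
        env = pd.DataFrame({"a": [3.0, 1.0, 5.0, 2.0, 4.0]})
        sre = fit_sre(env, q=0.0, variables=["a"])
        assert sre.bounds["a"] == (1.0, 5.0)

    def test_interpolated_quantile_envelope(self):
        env = pd.DataFrame({"a": np.arange(1.0, 101.0)})
        sre = fit_sre(env, q=0.025, variables=["a"])
        lo, hi = sre.bounds["a"]
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_variable_point_envelope(self):
        env = pd.DataFrame({"a": [2.0] * 6, "b": [1, 2, 3, 4, 5, 6.0]})
        sre = fit_sre(env, q=0.0, variables=["a", "b"])
        assert sre.bounds["a"] == (2.0, 2.0)
        pred = sre.predict(pd.DataFrame({"a": [2.0, 2.1], "b": [3.0, 3.0]}))
        np.testing.assert_array_equal(pred, [1.0, 0.0])

    def test_boundary_is_inclusive_and_outside_rejected(self):
        env = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]})
        sre = fit_sre(env, q=0.0, variables=["a"])
        pred = sre.predict(pd.DataFrame({"a": [1.0, 3.0, 5.0, 5.001]}))
        np.testing.assert_array_equal(pred, [1, 1, 1, 0])

    def test_missing_variable_rejected(self):
        env = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]})
        sre = fit_sre(env, q=0.0, variables=["a"])
        with pytest.raises(ValueError, match="missing"):
            sre.predict(pd.DataFrame({"b": [1.0]}))


class TestPseudoAbsences:
    def test_same_count_and_outside_envelope(self, small_stack, env_table):
        presence = env_table[env_table["label"] == 1]
        sre = fit_sre(presence)
        pa = sample_pseudo_absences(small_stack, sre, n=40, seed=1)
        assert len(pa) == 40
        assert (pa.frame["kind"] == "pseudo_absence").all()
        from fritniche.occurrences import extract_env

        env = extract_env(small_stack, pa)
        assert sre.predict(env).sum() == 0

    def test_all_suitable_raises(self, small_stack):
        sre = fit_sre(pd.DataFrame({
            "bio01": [-1e9, 1e9, 0, 0, 0], "bio12": [-1e9, 1e9, 0, 0, 0]}), q=0.0)
        with pytest.raises(ValueError, match="short"):
            sample_pseudo_absences(small_stack, sre, n=5, seed=1)

    def test_fixed_seed_reproducible(self, small_stack, env_table):
        sre = fit_sre(env_table[env_table["label"] == 1])
        a = sample_pseudo_absences(small_stack, sre, n=20, seed=9)
        b = sample_pseudo_absences(small_stack, sre, n=20, seed=9)
        assert a.frame.equals(b.frame)


class TestLogistic:
    def test_symmetric_data_gives_zero_intercept(self):
        env = pd.DataFrame({"x": [-1.0, -1, 1, 1], "label": [0, 0, 1, 1]})
        model = fit_logistic(env, degree=1)
        assert abs(model.coef[0]) < 1e-6

    def test_coefficient_recovery_within_three_se(self):
        rng = np.random.default_rng(21)
        n = 2000
        z = rng.normal(size=n)
        beta0, beta1 = -0.4, 1.3
        p = 1 / (1 + np.exp(-(beta0 + beta1 * z)))
        y = (rng.uniform(size=n) < p).astype(int)
        env = pd.DataFrame({"x": z, "label": y})
        model = fit_logistic(env, degree=1)
        # SEs from the inverse Fisher information at the fit
        X = model._design(env)
        mu = model.predict(env)
        w = mu * (1 - mu)
        cov = np.linalg.inv((X.T * w) @ X)
        se = np.sqrt(np.diag(cov))
        # the model standardizes x internally, so the true slope on the
        # fitted scale is beta1 * sd(x); the intercept shifts by the mean term
        sd = env["x"].to_numpy().std()
        mean = env["x"].to_numpy().mean()
        assert abs(model.coef[0] - (beta0 + beta1 * mean)) < 3 * se[0]
        assert abs(model.coef[1] - beta1 * sd) < 3 * se[1]

    def test_single_class_rejected(self):
        env = pd.DataFrame({"x": [1.0, 2.0], "label": [1, 1]})
        with pytest.raises(ValueError):
            fit_logistic(env)

    def test_perfect_separation_flagged_but_predicts(self):
        env = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)],
                            "label": np.r_[np.zeros(10), np.ones(10)].astype(int)})
        model = fit_logistic(env, degree=1, max_iter=50)
        assert model.separation_flag
        pred = model.predict(env)
        assert auc_score(pred, env["label"]) == 1.0

    def test_quadratic_fit_recovers_interior_optimum(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-3, 3, 1500)
        p = np.exp(-((x - 0.7) ** 2) / (2 * 0.8 ** 2))
        y = (rng.uniform(size=1500) < p).astype(int)
        env = pd.DataFrame({"x": x, "label": y})
        model = fit_logistic(env, degree=2)
        grid = pd.DataFrame({"x": np.linspace(-3, 3, 601)})
        pred = model.predict(grid)
        assert grid["x"][np.argmax(pred)] == pytest.approx(0.7, abs=0.2)


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, env):
        return np.full(len(env), self.value)


class _OneVar:
    def __init__(self, var):
        self.var = var

    def predict(self, env):
        x = env[self.var].to_numpy(dtype=float)
        return 1 / (1 + np.exp(-x))


class TestEnsemble:
    def test_auc_weight_normalization(self):
        ens = build_ensemble({"a": _Const(0.2), "b": _Const(0.8)},
                             {"a": 0.92, "b": 0.96}, auc_cutoff=0.9)
        assert ens.weights["a"] == pytest.approx(0.92 / 1.88, abs=1e-4)
        assert ens.weights["b"] == pytest.approx(0.96 / 1.88, abs=1e-4)
        assert ens.weights["a"] == pytest.approx(0.4894, abs=1e-4)

    def test_cutoff_excludes_weak_member(self):
        ens = build_ensemble({"a": _Const(0.2), "b": _Const(0.8)},
                             {"a": 0.95, "b": 0.85})
        assert set(ens.members) == {"a"}
        assert ens.weights["a"] == 1.0

    def test_identical_members_equal_single_member(self):
        env = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        ens = build_ensemble({"a": _OneVar("x"), "b": _OneVar("x")},
                             {"a": 0.95, "b": 0.95})
        np.testing.assert_allclose(ens.predict(env), _OneVar("x").predict(env))

    def test_no_passing_member_raises_with_advice(self):
        with pytest.raises(ValueError, match="relax"):
            build_ensemble({"a": _Const(0.5)}, {"a": 0.7})

    def test_prediction_is_convex_combination(self):
        env = pd.DataFrame({"x": np.linspace(-3, 3, 25)})
        members = {"a": _Const(0.1), "b": _OneVar("x"), "c": _Const(0.9)}
        ens = build_ensemble(members, {"a": 0.91, "b": 0.95, "c": 0.99})
        pred = ens.predict(env)
        stackp = np.vstack([m.predict(env) for m in members.values()])
        assert np.all(pred >= stackp.min(axis=0) - 1e-12)
        assert np.all(pred <= stackp.max(axis=0) + 1e-12)


class TestCrossValidate:
    def test_row_bookkeeping(self, env_table):
        scores = cross_validate(env_table, ("sre", "glm"), n_runs=5, seed=1)
        assert len(scores) == 10
        assert set(scores["algorithm"]) == {"sre", "glm"}

    def test_separable_species_perfect_glm_auc(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(5, 0.3, 60), rng.normal(-5, 0.3, 60)]
        env = pd.DataFrame({"x": x, "label": np.r_[np.ones(60), np.zeros(60)].astype(int)})
        scores = cross_validate(env, ("glm",), n_runs=5, seed=3)
        assert scores["auc"].mean() == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self, env_table):
        rng = np.random.default_rng(4)
        shuffled = env_table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        scores = cross_validate(shuffled, ("glm",), n_runs=15, seed=5)
        m = scores["auc"].mean()
        assert abs(m - 0.5) < 3 * scores["auc"].std() / np.sqrt(15) + 0.1


class TestRasterPrediction:
    def test_constant_stack_constant_map(self):
        stack = RasterStack(["x"], np.full((1, 6, 6), 0.3), 0.0, 6.0, 1.0, 1.0)
        grid = predict_raster(_OneVar("x"), stack)
        assert np.allclose(grid.values, 1 / (1 + np.exp(-0.3)))

    def test_nodata_propagates(self):
        data = np.full((1, 6, 6), 0.3)
        data[0, 2, 3] = np.nan
        stack = RasterStack(["x"], data, 0.0, 6.0, 1.0, 1.0)
        grid = predict_raster(_OneVar("x"), stack)
        assert np.isnan(grid.values[2, 3])
        assert np.isfinite(grid.values).sum() == 35

    def test_missing_layer_rejected(self):
        stack = RasterStack(["x"], np.zeros((1, 6, 6)), 0.0, 6.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="missing"):
            predict_raster(_OneVar("y"), stack, variables=["y"])

    def test_virtual_species_map_correlates_with_truth(self, small_stack,
                                                       small_truth, env_table):
        from scipy.stats import spearmanr

        res = EnsembleSDM(env_table, n_runs=5, seed=6).fit()
        pred = res.predict_raster(small_stack)
        mask = np.isfinite(pred.values) & np.isfinite(small_truth.true_suitability.values)
        rho = spearmanr(pred.values[mask], small_truth.true_suitability.values[mask]).statistic
        assert rho > 0.8


class TestImportanceAndResponse:
    def test_unused_variable_zero_importance(self):
        env = pd.DataFrame({"x": np.linspace(-2, 2, 40),
                            "z": np.random.default_rng(0).normal(size=40),
                            "label": ([0, 1] * 20)})
        imp = variable_importance(_OneVar("x"), env, n_perm=3, seed=1)
        row = imp.set_index("variable")
        assert row.loc["z", "raw"] == pytest.approx(0.0, abs=1e-12)

    def test_single_variable_model_gets_everything(self):
        env = pd.DataFrame({"x": np.linspace(-2, 2, 40), "label": [0, 1] * 20})
        imp = variable_importance(_OneVar("x"), env, n_perm=3, seed=1)
        assert imp["importance_pct"].iloc[0] == pytest.approx(100.0)

    def test_dominant_variable_identified(self, env_table):
        res = EnsembleSDM(env_table, algorithms=("glm",), n_runs=3, seed=7).fit()
        imp = res.variable_importance(n_perm=3, seed=8).set_index("variable")
        assert imp["importance_pct"].sum() == pytest.approx(100.0)

    def test_jackknife_mode_runs_and_normalizes(self, env_table):
        res = EnsembleSDM(env_table, algorithms=("glm",), n_runs=3, seed=9).fit()
        imp = variable_importance(res.ensemble, env_table, mode="jackknife", seed=1)
        assert imp["importance_pct"].sum() == pytest.approx(100.0)

    def test_flat_curve_for_ignoring_model(self, env_table):
        curve = response_curve(_OneVar("bio01"), env_table, "bio12", n_grid=21)
        assert np.ptp(curve.response) < 1e-12

    def test_two_point_curve(self, env_table):
        curve = response_curve(_OneVar("bio01"), env_table, "bio01", n_grid=2)
        assert curve.grid.size == 2

    def test_unknown_variable_rejected(self, env_table):
        with pytest.raises(ValueError, match="unknown"):
            response_curve(_OneVar("bio01"), env_table, "nope")


class TestSuitableRange:
    def test_tent_curve(self):
        grid = np.linspace(0, 10, 1001)
        resp = np.clip(0.8 - 0.15 * np.abs(grid - 5), 0, None)
        sr = suitable_range(ResponseCurve("v", grid, resp), threshold=0.5)
        assert sr.optimum == pytest.approx(5.0, abs=0.02)
        assert sr.lo == pytest.approx(3.0, abs=0.02)
        assert sr.hi == pytest.approx(7.0, abs=0.02)
        assert sr.max_probability == pytest.approx(0.8, abs=1e-6)

    def test_curve_below_threshold_empty_range(self):
        grid = np.linspace(0, 1, 11)
        sr = suitable_range(ResponseCurve("v", grid, np.full(11, 0.4)), 0.5)
        assert sr.empty
        assert np.isfinite(sr.optimum)

    def test_range_clipped_at_grid_edges(self):
        grid = np.linspace(0, 1, 11)
        sr = suitable_range(ResponseCurve("v", grid, np.full(11, 0.9)), 0.5)
        assert (sr.lo, sr.hi) == (0.0, 1.0)


class TestHabitatGradesAndAreas:
    def test_bin_boundaries(self, unit_grid):
        vals = np.array([[0.0, 0.2499, 0.25], [0.4999, 0.5, 0.7499],
                         [0.75, 0.9, 1.0]])
        grades = classify_habitat(unit_grid.like(vals))
        np.testing.assert_array_equal(grades.values,
                                      [[0, 0, 1], [1, 2, 2], [3, 3, 3]])

    def test_out_of_range_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            classify_habitat(unit_grid.like(np.full((3, 3), 1.2)))

    def test_all_high_is_hundred_percent(self, unit_grid):
        grades = unit_grid.like(np.full((3, 3), 3.0))
        stats = area_stats(grades)
        assert stats.set_index("grade").loc["high", "percent"] == pytest.approx(100.0)

    def test_area_conservation(self, unit_grid):
        rng = np.random.default_rng(1)
        grades = unit_grid.like(rng.integers(0, 4, size=(3, 3)).astype(float))
        stats = area_stats(grades)
        assert stats["km2"].sum() == pytest.approx(stats.attrs["domain_km2"], rel=1e-12)
        assert stats["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_domain_gives_zeros(self, unit_grid):
        grades = unit_grid.like(np.full((3, 3), 1.0))
        mask = unit_grid.like(np.zeros((3, 3)))
        stats = area_stats(grades, domain_mask=mask)
        assert (stats["km2"] == 0).all()

    def test_misaligned_mask_rejected(self, unit_grid):
        other = RasterGrid(np.zeros((3, 3)), west=10.0, north=3.0, dx=1.0, dy=1.0)
        with pytest.raises(ValueError, match="aligned"):
            area_stats(unit_grid.like(np.zeros((3, 3))), domain_mask=other)


class TestModelResults:
    def test_summary_and_weights(self, env_table):
        res = EnsembleSDM(env_table, n_runs=5, seed=10).fit()
        text = res.summary()
        assert "mean AUC" in text and "weight" in text
        assert sum(res.weights.values()) == pytest.approx(1.0)

    def test_ensemble_prediction_bounded_by_members(self, env_table):
        res = EnsembleSDM(env_table, n_runs=5, seed=10).fit()
        preds = {n: m.predict(env_table) for n, m in res.ensemble.members.items()}
        stackp = np.vstack(list(preds.values()))
        ens = res.predict(env_table)
        assert np.all(ens >= stackp.min(axis=0) - 1e-12)
        assert np.all(ens <= stackp.max(axis=0) + 1e-12)
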