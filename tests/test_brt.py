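"""Boosted-tree sub-models, CV tree selection, and ensemble diagnostics."""

import numpy as np
import pandas as pd
import pytest

from suitmap import brt
from suitmap.errors import ValidationError
from suitmap.raster import Raster, SuitabilityMap


def _toy_data(n=400, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    if signal:
        logit = 3.0 * X["a"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    else:
        y = rng.integers(0, 2, n)
    return X, y


class TestAssembleTraining:
    def test_features_equal_layer_lookups(self, small_world, small_presences,
                                          small_draws):
        stack = small_world["stack"]
        X, y, cells = brt.assemble_training(small_presences, small_draws[0],
                                            stack)
        for name in stack.names:
            np.testing.assert_array_equal(
                X[name].to_numpy(),
                stack.layers[name].values[cells[:, 0], cells[:, 1]])

    def test_nodata_cell_rejected(self, small_world, small_presences):
        stack = small_world["stack"]
        bad = np.argwhere(~stack.joint_valid())[:1]
        draw = brt.BackgroundDraw(1, 0, bad)
        with pytest.raises(ValidationError):
            brt.assemble_training(small_presences, draw, stack)


class TestFitBrt:
    def test_separable_data_reaches_training_auc_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": np.concatenate([rng.normal(-3, 0.5, 100),
                                               rng.normal(3, 0.5, 100)])})
        y = np.repeat([0, 1], 100)
        cfg = brt.BRTConfig(learning_rate=0.1, max_trees=200, step_size=50,
                            n_folds=2, min_obs_in_leaf=5)
        sub = brt.fit_brt(X, y, cfg, n_trees=200, seed=0, categorical=[])
        assert brt.roc_auc(y, sub.predict(X)) == 1.0

    def test_label_permutation_gives_chance_heldout_auc(self):
        # with labels independent of features, held-out discrimination
        # collapses to coin-flipping; averaged over permutations it sits at 1/2
        cfg = brt.BRTConfig(learning_rate=0.05, max_trees=100, step_size=50,
                            n_folds=2, min_obs_in_leaf=5)
        aucs = []
        for seed in range(5):
            X, y = _toy_data(600, seed=seed, signal=False)
            sub = brt.fit_brt(X.iloc[:400], y[:400], cfg, n_trees=100,
                              seed=seed, categorical=[])
            aucs.append(brt.roc_auc(y[400:], sub.predict(X.iloc[400:])))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_zero_learning_rate_rejected(self):
        with pytest.raises(ValidationError):
            brt.BRTConfig(learning_rate=0.0)

    def test_single_class_rejected(self):
        X, _ = _toy_data(50)
        cfg = brt.BRTConfig(max_trees=10, step_size=10)
        with pytest.raises(ValidationError):
            brt.fit_brt(X, np.ones(50, int), cfg, n_trees=10, seed=0)

    def test_row_order_invariance(self):
        X, y = _toy_data(300, seed=2)
        cfg = brt.BRTConfig(learning_rate=0.1, max_trees=50, step_size=50,
                            n_folds=2, min_obs_in_leaf=5)
        sub = brt.fit_brt(X, y, cfg, n_trees=50, seed=7, categorical=[])
        perm = np.random.default_rng(0).permutation(len(X))
        sub2 = brt.fit_brt(X.iloc[perm].reset_index(drop=True), y[perm], cfg,
                           n_trees=50, seed=7, categorical=[])
        probe = X.iloc[:50]
        np.testing.assert_allclose(sub.predict(probe), sub2.predict(probe))

    def test_intercept_is_log_odds_of_prevalence(self):
        X, y = _toy_data(300, seed=3)
        cfg = brt.BRTConfig(learning_rate=0.1, max_trees=10, step_size=10,
                            n_folds=2, min_obs_in_leaf=5)
        sub = brt.fit_brt(X, y, cfg, n_trees=10, seed=0, categorical=[])
        p = y.mean()
        assert sub.intercept == pytest.approx(np.log(p / (1 - p)))


class TestSelectNTrees:
    def test_noise_labels_select_near_first_increment(self):
        X, y = _toy_data(400, seed=4, signal=False)
        cfg = brt.BRTConfig(learning_rate=0.05, max_trees=300, step_size=50,
                            n_folds=5, min_obs_in_leaf=5)
        best, sel = brt.select_n_trees(X, y, cfg, seed=1, categorical=[])
        assert best <= 2 * cfg.step_size
        assert best <= cfg.max_trees

    @pytest.mark.filterwarnings("ignore:CV deviance minimum")
    def test_signal_improves_deviance_beyond_first_step(self):
        # slow shrinkage needs many trees, so the CV optimum must improve on
        # the first increment of the search
        X, y = _toy_data(600, seed=5, signal=True)
        cfg = brt.BRTConfig(learning_rate=0.01, max_trees=600, step_size=50,
                            n_folds=5, min_obs_in_leaf=5)
        best, sel = brt.select_n_trees(X, y, cfg, seed=1, categorical=[])
        assert best > cfg.step_size
        assert sel.cv_deviance[list(sel.steps).index(best)] < sel.cv_deviance[0]

    def test_boundary_minimum_warns(self):
        X, y = _toy_data(600, seed=6, signal=True)
        cfg = brt.BRTConfig(learning_rate=0.005, max_trees=100, step_size=50,
                            n_folds=3, min_obs_in_leaf=5)
        with pytest.warns(UserWarning, match="max_trees"):
            brt.select_n_trees(X, y, cfg, seed=0, categorical=[])

    def test_stratification_failure_raises(self):
        X, y = _toy_data(40, seed=7)
        y[:] = 0
        y[:3] = 1
        cfg = brt.BRTConfig(max_trees=10, step_size=10, n_folds=10)
        with pytest.raises(ValidationError, match="stratify"):
            brt.select_n_trees(X, y, cfg, seed=0, categorical=[])


class TestPredictMap:
    def test_zero_tree_model_is_constant_at_intercept(self, small_world):
        sub = brt.SubModel(None, ["temp_range"], [], 0, 0.1, intercept=1.0)
        smap = brt.predict_map(sub, small_world["stack"])
        expected = 1 / (1 + np.exp(-1.0))
        assert np.allclose(smap.mean.values[smap.valid], expected)

    def test_values_in_unit_interval(self, small_ensemble, small_world):
        smap = brt.predict_map(small_ensemble.submodels[0],
                               small_world["stack"])
        vals = smap.mean.values[smap.valid]
        assert vals.min() >= 0 and vals.max() <= 1

    def test_matches_row_by_row_prediction_oracle(self, small_ensemble,
                                                  small_world):
        stack = small_world["stack"]
        sub = small_ensemble.submodels[0]
        smap = brt.predict_map(sub, stack)
        rng = np.random.default_rng(0)
        rows, cols = np.nonzero(stack.joint_valid())
        pick = rng.choice(len(rows), 20, replace=False)
        for i, j in zip(rows[pick], cols[pick]):
            X1 = pd.DataFrame({n: [stack.layers[n].values[i, j]]
                               for n in sub.feature_names})
            assert smap.mean.values[i, j] == pytest.approx(
                sub.predict(X1)[0], rel=1e-12)

    def test_missing_layer_named_in_error(self, small_ensemble, small_world):
        stack = small_world["stack"].select(["elevation", "slope"])
        with pytest.raises(ValidationError, match="temp_range"):
            brt.predict_map(small_ensemble.submodels[0], stack)


class TestRocAuc:
    def test_four_point_example(self):
        assert brt.roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == 0.75

    def test_perfect_separation(self):
        assert brt.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        assert brt.roc_auc(y, -s) == pytest.approx(1 - brt.roc_auc(y, s))

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 8 + [0] * 12)
        s = rng.integers(0, 5, 20) / 4.0  # plenty of ties
        pairs = [(si, sj) for si, yi in zip(s, y) if yi
                 for sj, yj in zip(s, y) if not yj]
        expected = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                            for a, b in pairs])
        assert brt.roc_auc(y, s) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            brt.roc_auc([1, 1], [0.1, 0.2])


class TestRelativeInfluence:
    def test_contributions_sum_to_100(self, toy_submodel):
        ri = brt.relative_influence(toy_submodel)
        assert ri.sum() == pytest.approx(100.0, abs=1e-6)

    def test_stumps_on_one_variable_get_everything(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=300),
                          "b": np.zeros(300)})  # b is constant: unsplittable
        y = (X["a"] > 0).astype(int)
        cfg = brt.BRTConfig(learning_rate=0.3, tree_complexity=1,
                            max_trees=10, step_size=10, n_folds=2,
                            min_obs_in_leaf=5)
        sub = brt.fit_brt(X, y, cfg, n_trees=10, seed=0, categorical=[])
        ri = brt.relative_influence(sub)
        assert ri["a"] == pytest.approx(100.0)
        assert ri["b"] == 0.0

    def test_matches_tree_walk_oracle(self, toy_submodel):
        # independently re-accumulate per-split gains from the dumped trees
        dump = toy_submodel.booster.dump_model()
        gains = dict.fromkeys(toy_submodel.feature_names, 0.0)

        def walk(node):
            if "split_feature" in node:
                gains[toy_submodel.feature_names[node["split_feature"]]] += \
                    node["split_gain"]
                walk(node["left_child"])
                walk(node["right_child"])

        for tree in dump["tree_info"]:
            walk(tree["tree_structure"])
        total = sum(gains.values())
        expected = pd.Series({k: 100 * v / total for k, v in gains.items()})
        ri = brt.relative_influence(toy_submodel)
        pd.testing.assert_series_equal(ri.sort_index(), expected.sort_index(),
                                       rtol=1e-6, check_names=False)

    def test_zero_tree_model_rejected(self):
        sub = brt.SubModel(None, ["a"], [], 0, 0.1, 0.0)
        with pytest.raises(ValidationError):
            brt.relative_influence(sub)


class TestPartialDependence:
    def test_unsplittable_variable_gives_flat_curve(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=200),
                          "b": rng.normal(size=200)})
        y = (X["a"] > 0).astype(int)
        cfg = brt.BRTConfig(learning_rate=0.3, tree_complexity=1,
                            max_trees=20, step_size=20, n_folds=2,
                            min_obs_in_leaf=5)
        sub = brt.fit_brt(X[["a"]].assign(b=0.0), y, cfg, n_trees=20, seed=0,
                          categorical=[])
        curve = brt.partial_dependence(sub, "b", n_points=20)
        assert np.allclose(curve.mean_response, curve.mean_response[0])

    def test_single_feature_curve_equals_direct_prediction(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=300)})
        y = (X["a"] + rng.normal(0, 0.3, 300) > 0).astype(int)
        cfg = brt.BRTConfig(learning_rate=0.2, max_trees=50, step_size=50,
                            n_folds=2, min_obs_in_leaf=5)
        sub = brt.fit_brt(X, y, cfg, n_trees=50, seed=0, categorical=[])
        curve = brt.partial_dependence(sub, "a", n_points=25)
        direct = sub.predict(pd.DataFrame({"a": curve.grid_values}))
        np.testing.assert_allclose(curve.mean_response, direct, rtol=1e-10)

    def test_matches_clamp_and_average_oracle_on_50_rows(self, toy_submodel):
        sub = toy_submodel
        X50 = sub.train_X.iloc[:50].reset_index(drop=True)
        probe = brt.SubModel(sub.booster, sub.feature_names,
                             sub.categorical_features, sub.n_trees,
                             sub.learning_rate, sub.intercept, train_X=X50)
        curve = brt.partial_dependence(probe, "a", n_points=9)
        for k, v in enumerate(curve.grid_values):
            preds = []
            for i in range(len(X50)):
                row = X50.iloc[[i]].copy()
                row["a"] = v
                preds.append(sub.predict(row)[0])
            assert curve.mean_response[k] == pytest.approx(np.mean(preds),
                                                           rel=1e-10)

    def test_unknown_variable_rejected(self, toy_submodel):
        with pytest.raises(ValidationError):
            brt.partial_dependence(toy_submodel, "nope")


class TestEnsemble:
    def test_one_submodel_per_draw(self, small_ensemble, small_draws):
        assert small_ensemble.B == len(small_draws)
        assert [s.draw_index for s in small_ensemble.submodels] == \
            [d.index for d in small_draws]

    def test_bit_reproducible_under_base_seed(self, small_world,
                                              small_presences, small_draws,
                                              fast_config):
        again = brt.fit_ensemble(small_presences, small_draws,
                                 small_world["stack"], fast_config)
        ref = brt.fit_ensemble(small_presences, small_draws,
                               small_world["stack"], fast_config)
        for a, b in zip(again.submodels, ref.submodels):
            assert a.booster.model_to_string() == b.booster.model_to_string()

    def test_cv_auc_summary_has_both_axes(self, small_ensemble):
        summary = small_ensemble.cv_auc_summary()
        assert "across_folds" in summary and "across_submodels" in summary
        m, s = summary["across_folds"]
        assert 0.5 < m <= 1.0 and s >= 0.0


class TestEnsemblePredict:
    def test_identical_submodels_give_zero_sd(self, small_ensemble,
                                              small_world, fast_config):
        sub = small_ensemble.submodels[0]
        twin = brt.EnsembleModel([sub, sub], fast_config)
        smap = brt.ensemble_predict(twin, small_world["stack"])
        assert np.allclose(smap.sd.values[smap.valid], 0.0)

    def test_mean_and_sd_match_per_cell_loop_oracle(self, small_ensemble,
                                                    small_world, small_map):
        stack = small_world["stack"]
        maps = [brt.predict_map(s, stack).mean.values
                for s in small_ensemble.submodels]
        rng = np.random.default_rng(1)
        rows, cols = np.nonzero(stack.joint_valid())
        pick = rng.choice(len(rows), 30, replace=False)
        for i, j in zip(rows[pick], cols[pick]):
            vals = [m[i, j] for m in maps]
            assert small_map.mean.values[i, j] == pytest.approx(np.mean(vals))
            assert small_map.sd.values[i, j] == pytest.approx(
                np.std(vals), abs=1e-12)
            assert min(vals) - 1e-12 <= small_map.mean.values[i, j] \
                <= max(vals) + 1e-12


class TestEnsembleDiagnostics:
    def test_mean_contributions_sum_to_100(self, small_ensemble):
        rc = brt.ensemble_rc(small_ensemble)
        assert rc.table["mean_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (rc.table["ci_low"] <= rc.table["mean_pct"] + 1e-9).all()
        assert (rc.table["ci_high"] >= rc.table["mean_pct"] - 1e-9).all()

    def test_single_submodel_ci_width_zero(self, small_ensemble, fast_config):
        solo = brt.EnsembleModel([small_ensemble.submodels[0]], fast_config)
        rc = brt.ensemble_rc(solo)
        np.testing.assert_allclose(rc.table["ci_low"], rc.table["ci_high"])

    def test_dominant_variable_ranks_first(self, small_ensemble):
        rc = brt.ensemble_rc(small_ensemble)
        assert rc.table.iloc[0]["variable"] == "temp_range"

    def test_min_pct_filter(self, small_ensemble):
        rc = brt.ensemble_rc(small_ensemble, min_pct=1.0)
        assert (rc.table["mean_pct"] > 1.0).all()

    def test_curves_share_grid_and_average_pointwise(self, small_ensemble):
        curves = brt.ensemble_curves(small_ensemble, ["temp_range"],
                                     n_points=30)
        c = curves[0]
        assert c.per_model.shape == (small_ensemble.B, 30)
        np.testing.assert_allclose(c.mean_response, c.per_model.mean(axis=0))
        assert (np.diff(c.grid_values) > 0).all()
        assert c.mean_response.min() >= 0 and c.mean_response.max() <= 1


class TestSerialization:
    def test_save_load_round_trip_preserves_predictions(self, small_ensemble,
                                                        small_world, tmp_path):
        path = tmp_path / "model.json"
        brt.save_ensemble(small_ensemble, path)
        loaded = brt.load_ensemble(path, small_world["stack"])
        a = brt.ensemble_predict(small_ensemble, small_world["stack"])
        b = brt.ensemble_predict(loaded, small_world["stack"])
        np.testing.assert_allclose(a.mean.values, b.mean.values, atol=1e-12)
        assert loaded.config == small_ensemble.config
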