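"""Correlation/clustering, importance mechanisms and the experiment drivers."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from gagbind import analysis as A
from gagbind.dataset import FeatureTable, split_group_holdout, split_random, zscore_apply
from gagbind.models import ModelConfig, ModelFamily
from gagbind.synthetic import TableSpec, gen_feature_table, single_signal_spec


@pytest.fixture(scope="module")
def one_signal():
    """Target depends on exactly one feature (lie_elec), noiseless-ish."""
    spec = single_signal_spec(n_rows=3000, weight=3.0, noise_sigma=0.1, seed=5)
    return gen_feature_table(spec)[0]


class TestPearsonMatrix:
    def test_duplicated_column_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        t = FeatureTable(pd.DataFrame({"f1": x, "f2": x.copy()}), ("f1", "f2"), None)
        cm = A.pearson_matrix(t, include_target=False)
        assert cm.r.loc["f1", "f2"] == pytest.approx(1.0)

    def test_hand_evaluated_pearson(self):
        t = FeatureTable(pd.DataFrame({"f1": [1.0, 2, 3], "f2": [1.0, 2, 4]}),
                         ("f1", "f2"), None)
        cm = A.pearson_matrix(t, include_target=False)
        assert cm.r.loc["f1", "f2"] == pytest.approx(0.982, abs=5e-4)

    def test_negation_r_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        t = FeatureTable(pd.DataFrame({"f1": x, "f2": -x}), ("f1", "f2"), None)
        cm = A.pearson_matrix(t, include_target=False)
        assert cm.r.loc["f1", "f2"] == pytest.approx(-1.0)

    def test_target_appended(self, one_signal):
        cm = A.pearson_matrix(one_signal)
        assert cm.labels[-1] == "mmgbsa_kcal_mol"
        assert cm.r.loc["lie_elec", "mmgbsa_kcal_mol"] > 0.99
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T)


class TestClustering:
    def test_duplicated_features_merge_first(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 200))
        t = FeatureTable(pd.DataFrame({"f1": x, "f2": x.copy(), "f3": y}),
                         ("f1", "f2", "f3"), None)
        cm = A.cluster_features(A.pearson_matrix(t, include_target=False))
        first_merge = cm.linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_features_merge_near_one(self):
        rng = np.random.default_rng(3)
        t = FeatureTable(pd.DataFrame(rng.normal(size=(5000, 3)), columns=["f1", "f2", "f3"]),
                         ("f1", "f2", "f3"), None)
        cm = A.cluster_features(A.pearson_matrix(t, include_target=False))
        assert cm.linkage[-1][2] > 0.9

    def test_block_structure_recovered(self):
        spec = TableSpec(
            n_rows=20_000,
            feature_names=tuple(f"f{i}" for i in range(9)),
            latent_blocks=(
                (("f0", "f1", "f2"), 0.9),
                (("f3", "f4", "f5"), 0.9),
                (("f6", "f7", "f8"), 0.9),
            ),
            seed=8,
        )
        table, _ = gen_feature_table(spec)
        cm = A.cluster_features(A.pearson_matrix(table, include_target=False))
        flat = hierarchy.fcluster(cm.linkage, t=0.5, criterion="distance")
        blocks = {tuple(sorted(np.flatnonzero(flat == c))) for c in set(flat)}
        assert blocks == {(0, 1, 2), (3, 4, 5), (6, 7, 8)}


class TestImportance:
    def test_all_methods_rank_signal_feature_first(self, one_signal):
        reports = []
        linreg = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), one_signal)
        reports.append(A.coefficient_importance(linreg))
        forest = A.fit_on(ModelConfig(ModelFamily.RANDOM_FOREST, {"n_estimators": 50}), one_signal)
        reports.append(A.builtin_importance(forest))
        scaled = zscore_apply(one_signal, forest.scaler)
        reports.append(A.permutation_importance(forest, scaled, n_repeats=2, seed=0))
        train_raw, eval_raw = split_random(one_signal, 0.3, seed=0)
        reports.append(
            A.lofo_importance(ModelConfig(ModelFamily.LINEAR_REGRESSION), train_raw, eval_raw)
        )
        for report in reports:
            assert report.top_feature() == "lie_elec", report.method
            assert np.abs(report.normalized).max() == pytest.approx(1.0)

    def test_permutation_null_feature_near_zero(self, one_signal):
        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), one_signal)
        scaled = zscore_apply(one_signal, model.scaler)
        report = A.permutation_importance(model, scaled, n_repeats=3, seed=1)
        signal = dict(zip(report.features, report.raw))
        null_features = [f for f in report.features if f != "lie_elec"]
        assert max(abs(signal[f]) for f in null_features) < 0.02 * signal["lie_elec"]

    def test_permutation_matches_analytic_value(self):
        # shuffling the only feature of noiseless y = w x inflates MSE by 2 Var(y)
        spec = TableSpec(n_rows=50_000, feature_names=("f1",), weights={"f1": 1.0},
                         noise_sigma=1e-9, seed=2)
        table, _ = gen_feature_table(spec)
        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), table)
        scaled = zscore_apply(table, model.scaler)
        report = A.permutation_importance(model, scaled, n_repeats=3, seed=0)
        assert report.raw[0] == pytest.approx(2 * np.var(table.y), rel=0.05)

    def test_permutation_agrees_with_sklearn(self, one_signal):
        from sklearn.inspection import permutation_importance as sk_perm

        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), one_signal)
        scaled = zscore_apply(one_signal, model.scaler)
        ours = A.permutation_importance(model, scaled, n_repeats=10, seed=0)
        theirs = sk_perm(model.estimator, scaled.X, scaled.y, n_repeats=10,
                         random_state=0, scoring="neg_mean_squared_error")
        np.testing.assert_allclose(ours.raw, theirs.importances_mean, rtol=0.3, atol=1e-3)

    def test_duplicated_feature_dilutes_tree_importance(self):
        base = single_signal_spec(n_rows=4000, weight=3.0, noise_sigma=0.5, seed=6)
        dup = single_signal_spec(n_rows=4000, weight=3.0, noise_sigma=0.5, seed=6,
                                 duplicate_of="lie_elec")
        imp = {}
        for tag, spec in (("single", base), ("dup", dup)):
            table, _ = gen_feature_table(spec)
            model = A.fit_on(
                ModelConfig(ModelFamily.RANDOM_FOREST, {"n_estimators": 50}), table
            )
            report = A.builtin_importance(model)
            imp[tag] = dict(zip(report.features, report.raw))
        assert imp["dup"]["lie_elec"] < imp["single"]["lie_elec"]
        assert imp["dup"]["lie_elec_dup"] < imp["single"]["lie_elec"]

    def test_lofo_redundant_duplicate_near_zero(self):
        spec = single_signal_spec(n_rows=3000, weight=3.0, noise_sigma=0.1, seed=7,
                                  duplicate_of="lie_elec")
        table, _ = gen_feature_table(spec)
        train_raw, eval_raw = split_random(table, 0.3, seed=0)
        report = A.lofo_importance(ModelConfig(ModelFamily.LINEAR_REGRESSION),
                                   train_raw, eval_raw)
        by_name = dict(zip(report.features, report.raw))
        assert abs(by_name["lie_elec"]) < 0.05 * np.var(table.y)

    def test_lofo_sole_feature_loses_full_variance(self):
        spec = single_signal_spec(n_rows=3000, n_features=3, weight=3.0,
                                  noise_sigma=1e-6, seed=8)
        table, _ = gen_feature_table(spec)
        train_raw, eval_raw = split_random(table, 0.3, seed=0)
        report = A.lofo_importance(ModelConfig(ModelFamily.LINEAR_REGRESSION),
                                   train_raw, eval_raw)
        by_name = dict(zip(report.features, report.raw))
        assert by_name["lie_elec"] == pytest.approx(np.var(eval_raw.y), rel=0.1)

    def test_coefficient_normalization(self):
        report = A.ImportanceReport("COEFFICIENTS", "LINEAR_REGRESSION",
                                    ("a", "b"), np.array([2.0, -4.0]),
                                    A._normalize(np.array([2.0, -4.0])))
        np.testing.assert_allclose(report.normalized, [0.5, -1.0])

    def test_all_zero_weights_all_zero_report(self):
        np.testing.assert_array_equal(A._normalize(np.zeros(3)), np.zeros(3))

    def test_elasticnet_l1_sparsity_on_weak_signal(self):
        spec = TableSpec(n_rows=2000, feature_names=tuple(f"f{i}" for i in range(6)),
                         weights={"f0": 0.3}, noise_sigma=2.0, seed=9)
        table, _ = gen_feature_table(spec)
        model = A.fit_on(ModelConfig(ModelFamily.ELASTIC_NET), table)
        assert (model.estimator.coef_ == 0.0).any()

    def test_coefficient_importance_rejects_trees(self, one_signal):
        model = A.fit_on(ModelConfig(ModelFamily.RANDOM_FOREST, {"n_estimators": 20}),
                         one_signal)
        with pytest.raises(ValueError, match="unsupported method"):
            A.coefficient_importance(model)

    def test_shapley_substitution_is_noted(self, one_signal):
        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), one_signal)
        scaled = zscore_apply(one_signal, model.scaler)
        report = A.shapley_importance(model, scaled, n_repeats=2, seed=0)
        assert report.method == "SHAPLEY"
        assert "permutation" in report.note


class TestBenchmarkDrivers:
    def test_interaction_term_favors_nonlinear_models(self):
        spec = TableSpec(
            n_rows=6000,
            feature_names=("f1", "f2", "f3"),
            weights={"f3": 0.5},
            interactions=(("f1", "f2", 2.0),),
            noise_sigma=0.3,
            seed=10,
        )
        table, _ = gen_feature_table(spec)
        report = A.run_benchmark(
            table,
            families=(ModelFamily.LINEAR_REGRESSION, ModelFamily.GRADIENT_BOOST_TREES),
            n_reps=2,
            seed=0,
        )
        assert report.metric("GRADIENT_BOOST_TREES", True, "test", "r2") > \
            report.metric("LINEAR_REGRESSION", True, "test", "r2") + 0.2

    def test_single_cell_sweep_reduces_to_repetitions(self, one_signal):
        from gagbind.models import run_repetitions

        grid = A.fcnn_sweep(one_signal, None, architectures=((),), dropouts=(0.01,),
                            activations=("relu",), n_reps=1, seed=4)
        assert len(grid) == 1
        rep = run_repetitions(
            ModelConfig(ModelFamily.FCNN, {"hidden_sizes": (), "dropout_rate": 0.01,
                                           "activation": "relu"}, seed=4),
            one_signal, n_reps=1, seed=4,
        )
        assert grid["test_r2"].iloc[0] == pytest.approx(rep.mean["test"].r2)

    def test_reduction_curve_skips_tiny_subsets(self, one_signal, caplog):
        curve = A.data_reduction_curve(
            ModelConfig(ModelFamily.LINEAR_REGRESSION),
            one_signal.take(np.arange(600)),
            one_signal.take(np.arange(600, 1200)),
            k_values=(1, 5, 500),
            seed=0,
        )
        assert set(curve.points["k"]) == {1, 5}


@pytest.fixture(scope="module")
def trajectory_table():
    from gagbind.synthetic import paper_like_spec

    spec = paper_like_spec(n_rows=4000, n_validation_rows=0, n_trajectories=40, seed=13)
    return gen_feature_table(spec)[0]


class TestTrajectoryEvaluations:
    def test_oracle_model_perfect_trajectory_means(self, trajectory_table):
        # noiseless re-fit of the generating law acts as a near-oracle model
        model = A.fit_on(ModelConfig(ModelFamily.GRADIENT_BOOST_TREES), trajectory_table)
        ev = A.trajectory_mean_eval(model, trajectory_table)
        assert ev.pearson_r > 0.95
        assert len(ev.per_trajectory) == 40

    def test_mean_level_r_exceeds_frame_level_r(self, trajectory_table):
        from gagbind.dataset import compute_metrics

        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), trajectory_table)
        preds = A.predict_raw(model, trajectory_table)
        frame_r = np.corrcoef(preds, trajectory_table.y)[0, 1]
        ev = A.trajectory_mean_eval(model, trajectory_table)
        assert ev.pearson_r > frame_r

    def test_first_frame_weaker_than_trajectory_mean(self, trajectory_table):
        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), trajectory_table)
        ev_mean = A.trajectory_mean_eval(model, trajectory_table)
        screen = A.first_frame_screen(model, trajectory_table, threshold=-40.0)
        assert screen.mae > ev_mean.mae
        assert set(screen.per_trajectory["classified"]) <= {"strong", "weak"}

    def test_degenerate_threshold_single_class(self, trajectory_table):
        model = A.fit_on(ModelConfig(ModelFamily.LINEAR_REGRESSION), trajectory_table)
        screen = A.first_frame_screen(model, trajectory_table, threshold=1e9)
        assert (screen.per_trajectory["classified"] == "strong").all()
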