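"""Model construction, training behavior, and the classical baselines."""

import numpy as np
import pytest

from pulsebp.dataset import assemble, normalize, split
from pulsebp.models import (
    ModelConfig,
    TrainConfig,
    build_dnn_baseline,
    build_model,
    count_lstm_params,
    fit_ensemble,
    fit_mlr,
    predict,
    train,
)
from pulsebp.evaluation import summarize_errors
from pulsebp.synthetic import planted_feature_table


def planted_dataset(n=600, noise=1.0, seed=0):
    return normalize(split(assemble(planted_feature_table(n, noise, seed)), 0.8, seed))


class TestArchitecture:
    def test_model_id_topology_enforced(self):
        assert ModelConfig(model_id=1).n_lstm_layers == 4
        assert ModelConfig(model_id=1).residual is False
        assert ModelConfig(model_id=4).n_lstm_layers == 6
        with pytest.raises(ValueError):
            ModelConfig(model_id=2, n_lstm_layers=5)
        with pytest.raises(ValueError):
            ModelConfig(model_id="bogus")

    def test_residual_adds_no_parameters(self):
        d = 8
        m1 = build_model(ModelConfig(model_id=1, hidden_units=d), seed=0)
        m2 = build_model(ModelConfig(model_id=2, hidden_units=d), seed=0)
        assert m1.n_params == m2.n_params

    def test_extra_layer_costs_one_lstm(self):
        d = 8
        m2 = build_model(ModelConfig(model_id=2, hidden_units=d), seed=0)
        m3 = build_model(ModelConfig(model_id=3, hidden_units=d), seed=0)
        assert m3.n_params - m2.n_params == count_lstm_params(d, d)

    def test_dnn_parameter_count_closed_form(self):
        d, c = 16, 7
        net = build_dnn_baseline(n_features=c, hidden_units=d)
        expected = (c * d + d) + 3 * (d * d + d) + (d * 2 + 2)
        assert net.n_params == expected

    def test_build_deterministic_for_fixed_seed(self):
        a = build_model(ModelConfig(model_id=2, hidden_units=6), seed=5)
        b = build_model(ModelConfig(model_id=2, hidden_units=6), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)


class TestTraining:
    def test_lr_schedule_arithmetic(self):
        tcfg = TrainConfig()
        assert tcfg.lr_at(0) == pytest.approx(0.003)
        assert tcfg.lr_at(250) == pytest.approx(0.003 * 0.2**2)

    def test_loss_decreases_on_planted_mapping(self):
        ds = planted_dataset(400, seed=3)
        mcfg = ModelConfig(model_id=2, hidden_units=12, sequence_length=25)
        trained = train(
            build_model(mcfg, seed=0), ds, TrainConfig(max_epochs=8, batch_size=4, seed=0), mcfg
        )
        hist = trained.training_history
        assert hist[-1] < hist[0] * 0.5

    def test_training_deterministic_for_fixed_seed(self):
        ds = planted_dataset(200, seed=1)
        mcfg = ModelConfig(model_id=1, hidden_units=6, sequence_length=20)
        runs = []
        for _ in range(2):
            t = train(
                build_model(mcfg, seed=2), ds,
                TrainConfig(max_epochs=2, batch_size=4, seed=2), mcfg,
            )
            runs.append(t.training_history)
        assert runs[0] == runs[1]

    def test_unnormalized_dataset_rejected(self):
        ds = split(assemble(planted_feature_table(100)), 0.8, 0)
        with pytest.raises(ValueError):
            train(build_model(ModelConfig(model_id=1, hidden_units=4)), ds, TrainConfig())


@pytest.fixture(scope="module")
def small_trained():
    ds = planted_dataset(1000, seed=4)
    mcfg = ModelConfig(model_id=2, hidden_units=24, sequence_length=40)
    return ds, train(
        build_model(mcfg, seed=1), ds,
        TrainConfig(max_epochs=40, batch_size=5, seed=1), mcfg,
    )


class TestPrediction:

    def test_planted_mapping_held_out_mae(self, small_trained):
        ds, trained = small_trained
        pred = predict(trained, ds.features)
        truth = ds.denormalize_targets(ds.targets)
        cols = ds.test_columns
        for row in (0, 1):
            mae = summarize_errors(pred[row, cols], truth[row, cols]).mae_mmhg
            assert mae < 3.0

    def test_constant_input_reaches_constant_output(self, small_trained):
        ds, trained = small_trained
        window = trained.config.sequence_length
        const = np.tile(ds.features[:, :1], (1, window))
        out = predict(trained, const)
        # mid-window steps are past the burn-in of both BiLSTM directions,
        # so consecutive outputs settle toward a fixed point (mmHg scale)
        mid = out[:, window // 2 - 5 : window // 2 + 5]
        assert np.max(np.abs(np.diff(mid, axis=1))) < 0.5

    def test_feature_dimension_mismatch_rejected(self, small_trained):
        _, trained = small_trained
        with pytest.raises(ValueError):
            predict(trained, np.zeros((5, 10)))


class TestMLR:
    def test_noiseless_linear_recovery_is_exact(self):
        ds = planted_dataset(300, noise=0.0, seed=6)
        model = fit_mlr(ds)
        pred = model.predict(ds.features[:, ds.test_columns])
        truth = ds.denormalize_targets(ds.targets)[:, ds.test_columns]
        assert np.max(np.abs(pred - truth)) < 1e-6

    def test_noisy_mae_matches_half_normal_oracle(self):
        # residual sd 1 mmHg -> optimal MAE = sqrt(2/pi) ~= 0.798
        ds = planted_dataset(4000, noise=1.0, seed=7)
        model = fit_mlr(ds)
        pred = model.predict(ds.features[:, ds.test_columns])
        truth = ds.denormalize_targets(ds.targets)[:, ds.test_columns]
        mae = summarize_errors(pred[0], truth[0]).mae_mmhg
        assert mae == pytest.approx(np.sqrt(2 / np.pi), abs=0.1)

    def test_collinear_design_raises_named_error(self):
        table = planted_feature_table(100, seed=8)
        table["dv"] = 2.0 * table["sv"]  # exact collinearity
        ds = normalize(split(assemble(table), 0.8, 0))
        with pytest.raises(ValueError, match="collinear"):
            fit_mlr(ds)

    def test_underdetermined_rejected(self):
        ds = planted_dataset(9, seed=9)  # 7 train rows < p+1 = 8
        with pytest.raises(ValueError, match="training rows"):
            fit_mlr(ds)


@pytest.fixture(scope="module")
def nonlinear_dataset():
    table = planted_feature_table(2000, 0.0, seed=10)
    table["sbp"] = 100.0 + 40.0 * np.sin(4.0 * table["ptt"]) ** 2 + 20.0
    table["dbp"] = table["sbp"] - 40.0
    return normalize(split(assemble(table), 0.8, 0))


class TestEnsembles:
    def test_bagging_beats_mlr_on_nonlinear_mapping(self, nonlinear_dataset):
        ds = nonlinear_dataset
        truth = ds.denormalize_targets(ds.targets)[:, ds.test_columns]
        bag = fit_ensemble(ds, "bagging", n_estimators=30, seed=0)
        mlr = fit_mlr(ds)
        mae_bag = summarize_errors(
            bag.predict(ds.features[:, ds.test_columns])[0], truth[0]
        ).mae_mmhg
        mae_mlr = summarize_errors(
            mlr.predict(ds.features[:, ds.test_columns])[0], truth[0]
        ).mae_mmhg
        assert mae_bag < mae_mlr

    def test_single_tree_without_bootstrap_is_a_plain_tree(self):
        from sklearn.tree import DecisionTreeRegressor

        ds = planted_dataset(200, seed=11)
        bag = fit_ensemble(ds, "bagging", n_estimators=1, bootstrap=False, seed=0)
        x = ds.features[:, ds.train_columns].T
        tree = DecisionTreeRegressor(random_state=0).fit(x, ds.targets[0, ds.train_columns])
        # both memorize the training set exactly; compare fitted values
        assert np.allclose(bag.estimators[0].predict(x), tree.predict(x))

    def test_zero_stage_boosting_predicts_training_mean(self):
        ds = planted_dataset(200, seed=12)
        model = fit_ensemble(ds, "lsboost", n_estimators=0)
        scaled = model.estimators[0].predict(ds.features[:, ds.test_columns].T)
        assert np.allclose(scaled, ds.targets[0, ds.train_columns].mean())

    def test_unknown_kind_rejected(self):
        ds = planted_dataset(200, seed=13)
        with pytest.raises(ValueError, match="kind"):
            fit_ensemble(ds, "stacking")


class TestDNNBaseline:
    def test_converges_on_planted_linear_mapping(self):
        ds = planted_dataset(1000, seed=14)
        mcfg = ModelConfig(model_id="dnn", hidden_units=64, sequence_length=40)
        trained = train(
            build_model(mcfg, seed=0), ds,
            TrainConfig(max_epochs=80, batch_size=10, seed=0), mcfg,
        )
        pred = predict(trained, ds.features)
        truth = ds.denormalize_targets(ds.targets)
        cols = ds.test_columns
        assert summarize_errors(pred[0, cols], truth[0, cols]).mae_mmhg < 3.0
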