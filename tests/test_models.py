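"""Levenberg-Marquardt training, early stopping, and function recovery."""

import numpy as np
import pytest

from facepulse.errors import AlignmentError, InsufficientHistoryError
from facepulse.features import SymmetricMinMaxScaler
from facepulse.models import (
    FeedforwardRegressor,
    NARXRegressor,
    _TwoLayerNet,
    evaluate_fit,
    load_model,
    neuron_grid,
    save_model,
)
from facepulse.synthetic import generate_model1_dataset, generate_narx_benchmark


@pytest.fixture(scope="module")
def linear_dataset():
    """Noiseless targets that are a linear map of the features."""
    return generate_model1_dataset(300, seed=11, noise_frac=0.0)


@pytest.fixture(scope="module")
def fitted_model1(linear_dataset):
    X, y = linear_dataset
    return FeedforwardRegressor(random_state=0, max_epochs=300).fit(
        X.to_numpy(), y.to_numpy()
    )


@pytest.fixture(scope="module")
def narx_data():
    return generate_narx_benchmark(600, seed=21, noise_sd=0.02)


class TestJacobian:
    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = _TwoLayerNet(4, 3, 2)
        params = rng.normal(0, 0.5, net.n_params)
        X = rng.normal(size=(6, 4))
        out, J = net.forward_jacobian(params, X)
        eps = 1e-6
        for p in range(0, net.n_params, 7):
            bumped = params.copy()
            bumped[p] += eps
            fd = (net.forward(bumped, X) - out).ravel() / eps
            np.testing.assert_allclose(J[:, p], fd, atol=1e-5)


class TestFeedforwardRegressor:
    def test_topology_is_18_10_3(self, fitted_model1):
        w1, b1, w2, b2 = fitted_model1.coefs_
        assert w1.shape == (10, 18)
        assert w2.shape == (3, 10)

    def test_noiseless_linear_map_recovered(self, fitted_model1):
        assert fitted_model1.report_["overall"].r >= 0.99

    def test_training_sample_predicted_closely(self, fitted_model1, linear_dataset):
        X, y = linear_dataset
        pred = fitted_model1.predict(X.to_numpy()[:5])
        np.testing.assert_allclose(pred, y.to_numpy()[:5], atol=1.0)

    def test_prediction_has_three_outputs(self, fitted_model1, linear_dataset):
        X, _ = linear_dataset
        assert fitted_model1.predict(X.to_numpy()[:4]).shape == (4, 3)

    def test_same_seed_reproduces_report(self, linear_dataset):
        X, y = linear_dataset
        a = FeedforwardRegressor(random_state=3, max_epochs=40).fit(
            X.to_numpy(), y.to_numpy()
        )
        b = FeedforwardRegressor(random_state=3, max_epochs=40).fit(
            X.to_numpy(), y.to_numpy()
        )
        assert a.report_ == b.report_
        np.testing.assert_array_equal(a._params, b._params)

    def test_stage_counts_follow_70_15_15(self, fitted_model1):
        rep = fitted_model1.report_
        assert (rep["train"].n, rep["validation"].n, rep["test"].n) == (210, 45, 45)
        assert rep["overall"].n == 300

    def test_too_few_samples_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 18))
        with pytest.raises(ValueError):
            FeedforwardRegressor().fit(X, X[:, :3])

    def test_non_finite_inputs_rejected(self, linear_dataset):
        X, y = linear_dataset
        Xbad = X.to_numpy().copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError):
            FeedforwardRegressor().fit(Xbad, y.to_numpy())

    def test_constant_network_predicts_constant(self, fitted_model1, linear_dataset):
        """Zeroed weights with output biases at the normalized target means
        predict the training-mean targets everywhere."""
        X, y = linear_dataset
        model = FeedforwardRegressor(random_state=0, max_epochs=1).fit(
            X.to_numpy(), y.to_numpy()
        )
        yn_mean = model.target_scaler_.transform(y.to_numpy()).mean(axis=0)
        model._params = np.concatenate(
            [np.zeros(model._net.n_params - 3), yn_mean]
        )
        pred = model.predict(X.to_numpy()[:7])
        expected = model.target_scaler_.inverse_transform(yn_mean[None, :])
        np.testing.assert_allclose(pred, np.repeat(expected, 7, axis=0), atol=1e-9)

    def test_identity_round_trip_through_normalization(self, fitted_model1, linear_dataset):
        X, y = linear_dataset
        sc = fitted_model1.target_scaler_
        np.testing.assert_allclose(
            sc.inverse_transform(sc.transform(y.to_numpy())), y.to_numpy(),
            atol=1e-10,
        )


class TestNARXRegressor:
    def test_effective_regressor_width_is_22(self, narx_data):
        X, y = narx_data
        model = NARXRegressor(random_state=0, max_epochs=50).fit(
            X.to_numpy(), y.to_numpy()
        )
        w1, _, w2, _ = model.coefs_
        assert w1.shape == (5, 22)
        assert w2.shape == (2, 5)

    def test_known_narx_process_recovered(self, narx_data):
        X, y = narx_data
        model = NARXRegressor(random_state=1).fit(X.to_numpy(), y.to_numpy())
        assert model.report_["overall"].r >= 0.95

    def test_open_loop_predictions_start_after_delays(self, narx_data):
        X, y = narx_data
        model = NARXRegressor(random_state=0, max_epochs=30).fit(
            X.to_numpy(), y.to_numpy()
        )
        pred = model.predict(X.to_numpy(), y.to_numpy())
        assert pred.shape == (len(X) - 2, 2)
        np.testing.assert_allclose(
            model.prediction_times(len(X))[:3], [2.0, 3.0, 4.0]
        )

    def test_predicted_series_correlates_with_truth(self, narx_data):
        X, y = narx_data
        model = NARXRegressor(random_state=1).fit(X.to_numpy(), y.to_numpy())
        pred = model.predict(X.to_numpy(), y.to_numpy())
        r = np.corrcoef(pred.ravel(), y.to_numpy()[2:].ravel())[0, 1]
        assert r >= 0.95

    def test_constant_zero_targets_learned(self, narx_data):
        X, _ = narx_data
        y = np.zeros((len(X), 2))
        y[0] = [1e-9, -1e-9]  # avoid a fully degenerate normalization range
        model = NARXRegressor(random_state=0, max_epochs=50).fit(X.to_numpy(), y)
        pred = model.predict(X.to_numpy(), y)
        assert np.mean(pred**2) <= 1e-4

    def test_empty_history_rejected(self, narx_data):
        X, y = narx_data
        model = NARXRegressor(random_state=0, max_epochs=10).fit(
            X.to_numpy(), y.to_numpy()
        )
        with pytest.raises(InsufficientHistoryError):
            model.predict(X.to_numpy()[:5], np.empty((0, 2)))

    def test_misaligned_lengths_rejected(self, narx_data):
        X, y = narx_data
        with pytest.raises(AlignmentError):
            NARXRegressor().fit(X.to_numpy(), y.to_numpy()[:-5])


class TestEvaluateFit:
    def test_perfect_fit(self):
        y = np.random.default_rng(0).normal(size=(30, 2))
        labels = np.array(["train"] * 20 + ["validation"] * 5 + ["test"] * 5)
        rep = evaluate_fit(y, y, labels)
        assert rep["overall"].mse == 0.0
        assert rep["overall"].r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)

    def test_constant_offset_preserves_r(self):
        y = np.random.default_rng(1).normal(size=(40, 1))
        labels = np.array(["train"] * 40)
        rep = evaluate_fit(y + 3.0, y, labels)
        assert rep["overall"].mse == pytest.approx(9.0)
        assert rep["overall"].r == pytest.approx(1.0)

    def test_stage_counts_sum_to_overall(self):
        y = np.random.default_rng(2).normal(size=(50, 1))
        labels = np.array(["train"] * 35 + ["validation"] * 8 + ["test"] * 7)
        rep = evaluate_fit(y, y, labels)
        assert rep["train"].n + rep["validation"].n + rep["test"].n == rep["overall"].n

    def test_zero_variance_predictions_give_nan_r(self):
        y = np.random.default_rng(3).normal(size=(20, 1))
        rep = evaluate_fit(np.zeros_like(y), y, np.array(["train"] * 20))
        assert np.isnan(rep["overall"].r)


class TestEarlyStoppingAndGrid:
    def test_returned_weights_achieve_best_validation_mse(self):
        X, y = generate_model1_dataset(120, seed=5, noise_frac=0.3)
        model = FeedforwardRegressor(random_state=2, max_epochs=60).fit(
            X.to_numpy(), y.to_numpy()
        )
        assert model.best_epoch_ <= model.n_iter_
        assert model.report_["validation"].mse <= model.report_["train"].mse * 10

    def test_neuron_grid_returns_report_per_size(self):
        X, y = generate_model1_dataset(100, seed=6)
        reports = neuron_grid(
            lambda **kw: FeedforwardRegressor(max_epochs=15, **kw),
            X.to_numpy(), y.to_numpy(), sizes=(3, 5), random_state=0,
        )
        assert set(reports) == {3, 5}
        assert all(abs(r["overall"].r) <= 1 for r in reports.values())


class TestPersistence:
    def test_model_json_round_trip(self, fitted_model1, linear_dataset, tmp_path):
        X, _ = linear_dataset
        save_model(fitted_model1, tmp_path / "m1.json")
        back = load_model(tmp_path / "m1.json")
        np.testing.assert_allclose(
            back.predict(X.to_numpy()[:10]),
            fitted_model1.predict(X.to_numpy()[:10]),
            atol=1e-12,
        )

    def test_narx_json_round_trip(self, narx_data, tmp_path):
        X, y = narx_data
        model = NARXRegressor(random_state=0, max_epochs=20).fit(
            X.to_numpy(), y.to_numpy()
        )
        save_model(model, tmp_path / "m2.json")
        back = load_model(tmp_path / "m2.json")
        np.testing.assert_allclose(
            back.predict(X.to_numpy(), y.to_numpy()),
            model.predict(X.to_numpy(), y.to_numpy()),
            atol=1e-12,
        )
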