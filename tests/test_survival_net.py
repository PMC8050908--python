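import numpy as np
import pytest

from coxdist import (
    NetworkSpec,
    dist_loss,
    fit_distribution_params,
    generate_times,
    predict_survival_time,
    predicted_time_histogram,
    rmse,
    simulate_cohort,
    train_distribution_net,
    train_hazard,
)
from coxdist import SyntheticSpec
from coxdist.errors import TrainingError, ValidationError
from coxdist.survival_net import SurvivalTimeModel
from coxdist.hazard_net import HazardModel
from coxdist._nn import MLP


def _constant_output_models(h_value: float, y_pred_value: float):
    """Hand-built hazard + survival models emitting fixed h and y_pred."""
    hnet = MLP(2, (1,), dropout_rate=0.0, rng=np.random.default_rng(0))
    hnet.weights[0][...] = 0.0
    hnet.biases[0][...] = h_value
    hazard = HazardModel(NetworkSpec(layer_widths=(1,), dropout_rate=0.0),
                         hnet, ["a", "b"], np.array([]))
    dnet = MLP(2, (1,), dropout_rate=0.0, rng=np.random.default_rng(1))
    dnet.weights[0][...] = 0.0
    # softplus(raw) * scale = y_pred_value with scale = y_pred_value
    dnet.biases[0][...] = np.log(np.e - 1.0)
    model = SurvivalTimeModel(hazard, dnet, y_pred_value,
                              NetworkSpec(layer_widths=(1,), dropout_rate=0.0),
                              np.array([]))
    return model


class TestDistLoss:
    def test_exact_fit_is_zero(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 100, size=20)
        h = rng.normal(size=20)
        assert dist_loss(y * np.exp(h), y, h) == pytest.approx(0.0, abs=1e-18)

    def test_hand_example_unit_hazard(self):
        assert dist_loss([5.0], [10.0], [0.0]) == pytest.approx(25.0)

    def test_hand_example_hazard_ratio_two(self):
        assert dist_loss([10.0], [10.0], [np.log(2.0)]) == pytest.approx(25.0)

    def test_misaligned_rejected(self):
        with pytest.raises(ValidationError):
            dist_loss([1.0, 2.0], [1.0], [0.0])


class TestPredictTime:
    def test_unit_hazard_ratio(self):
        model = _constant_output_models(h_value=0.0, y_pred_value=10.0)
        np.testing.assert_allclose(
            predict_survival_time(model, np.zeros((3, 2))), 10.0, rtol=1e-12
        )

    def test_hazard_ratio_two_halves_time(self):
        model = _constant_output_models(h_value=np.log(2.0), y_pred_value=10.0)
        np.testing.assert_allclose(
            predict_survival_time(model, np.zeros((3, 2))), 5.0, rtol=1e-12
        )

    def test_time_decreases_as_hazard_grows(self):
        times = [
            predict_survival_time(_constant_output_models(h, 10.0), np.zeros((1, 2)))[0]
            for h in (-1.0, 0.0, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(times, times[1:]))

    def test_row_order_invariance(self, survival_model, holdout_cohort):
        ds, _ = holdout_cohort
        X = ds.covariates[:40]
        perm = np.random.default_rng(1).permutation(40)
        np.testing.assert_array_equal(
            predict_survival_time(survival_model, X[perm]),
            predict_survival_time(survival_model, X)[perm],
        )

    def test_predicted_times_positive(self, survival_model, holdout_cohort):
        ds, _ = holdout_cohort
        assert (predict_survival_time(survival_model, ds.covariates) > 0).all()


class TestTraining:
    def test_hazard_weights_frozen(self, recovery_cohort, hazard_model):
        ds, _ = recovery_cohort
        before = hazard_model.weights_hash()
        train_distribution_net(ds, hazard_model,
                               NetworkSpec(seed=1, learning_rate=1e-2, epochs=200))
        assert hazard_model.weights_hash() == before

    def test_training_loss_decreases_smoothed(self, survival_model):
        trace = survival_model.train_trace
        k = max(len(trace) // 10, 1)
        smoothed = np.convolve(trace, np.ones(k) / k, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_all_censored_rejected(self, hazard_model, recovery_cohort):
        ds, _ = recovery_cohort
        censored = ds.subset(np.arange(ds.n))
        censored.event[:] = 0
        with pytest.raises(TrainingError):
            train_distribution_net(censored, hazard_model, NetworkSpec(epochs=5))

    def test_beats_exponential_baseline_on_rmse(self):
        """Held-out RMSE of the learned predictor vs. the exponential
        generator, averaged over 5 seeds on fresh cohorts."""
        wins = []
        for seed in range(5):
            tr, _ = simulate_cohort(SyntheticSpec(
                n=1200, beta=(1.0, -1.0, 0.5, 0.0, 0.0), censor_rate=0.3, seed=100 + seed))
            te, te_truth = simulate_cohort(SyntheticSpec(
                n=400, beta=(1.0, -1.0, 0.5, 0.0, 0.0), censor_rate=0.0, seed=200 + seed))
            spec = NetworkSpec(seed=seed, learning_rate=1e-2, epochs=1000)
            hz = train_hazard(tr, spec)
            model = train_distribution_net(tr, hz, spec)
            prop = rmse(model.predict_time(te.covariates), te_truth.true_time)
            cfg = fit_distribution_params(tr, "exponential",
                                          log_risks=hz.predict(tr.covariates), seed=seed)
            base = rmse(generate_times(cfg, hz.predict(te.covariates)), te_truth.true_time)
            wins.append(prop - base)
        assert np.mean(wins) < 0


class TestHistogram:
    def test_conservation_and_coverage(self, survival_model, holdout_cohort):
        ds, _ = holdout_cohort
        table = predicted_time_histogram(survival_model, ds.covariates, bins=15)
        assert table["count"].sum() == ds.n
        values = survival_model.predict_y_pred(ds.covariates)
        assert table["bin_left"].iloc[0] == pytest.approx(values.min())
        assert table["bin_right"].iloc[-1] == pytest.approx(values.max())

    def test_constant_output_single_bin(self):
        model = _constant_output_models(0.0, 10.0)
        table = predicted_time_histogram(model, np.zeros((30, 2)), bins=10)
        assert (table["count"] > 0).sum() == 1

    def test_survival_time_variant(self, survival_model, holdout_cohort):
        ds, _ = holdout_cohort
        table = predicted_time_histogram(survival_model, ds.covariates,
                                         bins=10, which="survival_time")
        assert table["count"].sum() == ds.n


class TestSerialization:
    def test_save_load_round_trip(self, survival_model, holdout_cohort, tmp_path):
        ds, _ = holdout_cohort
        path = tmp_path / "model.npz"
        survival_model.save(path)
        loaded = SurvivalTimeModel.load(path)
        np.testing.assert_array_equal(
            loaded.predict_time(ds.covariates[:20]),
            survival_model.predict_time(ds.covariates[:20]),
        )
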