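"""BP-ANN level regression: gradients, convergence, parameter recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from chromanose import chemometrics, regressor as reg, synthgen
from chromanose.errors import DomainError
from chromanose.regressor import _loss_and_grads


def _random_net(rng, p=3, h=4):
    return (
        rng.normal(scale=0.5, size=(h, p)),
        rng.normal(scale=0.5, size=h),
        rng.normal(scale=0.5, size=(1, h)),
        rng.normal(scale=0.5, size=1),
    )


class TestGradients:
    def test_analytic_matches_central_finite_differences(self, rng):
        W1, b1, W2, b2 = _random_net(rng)
        X = rng.uniform(size=(7, 3))
        y = rng.uniform(size=(7, 1))
        _, grads = _loss_and_grads(W1, b1, W2, b2, X, y)
        params = [W1, b1, W2, b2]
        eps = 1e-6
        for arr, grad in zip(params, grads, strict=True):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp, _ = _loss_and_grads(W1, b1, W2, b2, X, y)
                arr[ix] = orig - eps
                lm, _ = _loss_and_grads(W1, b1, W2, b2, X, y)
                arr[ix] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(abs(numeric), abs(grad[ix]), 1e-8)
                assert abs(numeric - grad[ix]) / denom < 1e-5

    def test_single_step_reduces_single_sample_error(self, rng):
        # momentum 0, one sample: a small enough step descends
        X = rng.uniform(size=(1, 3))
        y = rng.uniform(size=(1,))
        hyper = reg.BPANNHyperparams(learning_rate=0.01, momentum=0.0, max_epochs=1)
        model = reg.bpann_train(X, y, h=4, seed=0, hyper=hyper)
        # loss_curve holds the pre-update loss; recompute after the update
        Xn = chemometrics.minmax_apply(model.norm_in, X)
        yn = chemometrics.minmax_apply(model.norm_out, y.reshape(-1, 1))
        after, _ = _loss_and_grads(model.W1, model.b1, model.W2, model.b2, Xn, yn)
        # degenerate single-row normalization maps to constants; assert no increase
        assert after <= model.loss_curve[0] + 1e-15


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        X = rng.uniform(size=(10, 3))
        y = rng.uniform(size=10)
        hyper = reg.BPANNHyperparams(learning_rate=0.0, momentum=0.0, max_epochs=50)
        model = reg.bpann_train(X, y, h=3, seed=1, hyper=hyper)
        fresh = np.random.default_rng(1)
        W1 = fresh.uniform(-0.5, 0.5, size=(3, 3))
        np.testing.assert_array_equal(model.W1, W1)

    def test_seed_determinism(self, rng):
        X = rng.uniform(size=(12, 4))
        y = rng.uniform(size=12)
        hyper = reg.BPANNHyperparams(max_epochs=200)
        a = reg.bpann_train(X, y, h=4, seed=5, hyper=hyper)
        b = reg.bpann_train(X, y, h=4, seed=5, hyper=hyper)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.loss_curve, b.loss_curve)

    def test_noiseless_linear_target_reaches_target_error_early(self, rng):
        X = rng.uniform(size=(30, 4))
        y = X.mean(axis=1)
        model = reg.bpann_train(X, y, h=4, seed=0)
        assert model.converged
        assert model.final_mse <= 2e-4
        assert model.final_epoch < 10_000

    def test_running_minimum_of_loss_curve_is_monotone(self, rng):
        X = rng.uniform(size=(20, 3))
        y = rng.uniform(size=20)
        hyper = reg.BPANNHyperparams(max_epochs=300)
        model = reg.bpann_train(X, y, h=4, seed=2, hyper=hyper)
        run_min = np.minimum.accumulate(model.loss_curve)
        assert (np.diff(run_min) <= 0).all()

    def test_levels_outside_unit_interval_rejected(self, rng):
        with pytest.raises(DomainError):
            reg.bpann_train(rng.uniform(size=(5, 2)), np.array([0, 0.5, 1.0, 1.5, 0.2]), h=2)


class TestPrediction:
    def test_converged_training_rmse_bounded_by_stopping_rule(self, rng):
        X = rng.uniform(size=(30, 4))
        y = 0.2 + 0.6 * X.mean(axis=1)
        model = reg.bpann_train(X, y, h=5, seed=0)
        assert model.converged
        yn = chemometrics.minmax_apply(model.norm_out, y.reshape(-1, 1))
        pred_n = chemometrics.minmax_apply(
            model.norm_out, reg.bpann_predict(model, X).reshape(-1, 1)
        )
        assert np.sqrt(np.mean((pred_n - yn) ** 2)) <= np.sqrt(2e-4) + 1e-9

    def test_constant_network_predicts_inverse_normalized_bias(self, rng):
        X = rng.uniform(size=(8, 3))
        y = rng.uniform(size=8)
        model = reg.bpann_train(
            X, y, h=3, seed=0,
            hyper=reg.BPANNHyperparams(learning_rate=0.0, max_epochs=1),
        )
        model.W1[:] = 0.0
        model.b1[:] = 0.0
        model.W2[:] = 0.0
        model.b2[:] = 0.7
        expected = chemometrics.minmax_invert(model.norm_out, np.array([[0.7]]))[0, 0]
        np.testing.assert_allclose(reg.bpann_predict(model, X), expected)

    def test_noiseless_parameter_recovery(self, noiseless_model):
        # nine component scores into five hidden nodes: the study topology
        ds = synthgen.generate_dataset(model=noiseless_model, seed=3)
        pca = chemometrics.pca_fit(ds.X)
        scores = chemometrics.pca_transform(pca, ds.X, 9)
        model = reg.bpann_train(scores, ds.levels, h=5, seed=0)
        rmse = np.sqrt(np.mean((reg.bpann_predict(model, scores) - ds.levels) ** 2))
        assert rmse < 0.02

    def test_predictions_monotone_in_level_on_noiseless_data(self, noiseless_model):
        ds = synthgen.generate_dataset(model=noiseless_model, seed=3)
        pca = chemometrics.pca_fit(ds.X)
        scores = chemometrics.pca_transform(pca, ds.X, 9)
        model = reg.bpann_train(scores, ds.levels, h=5, seed=0)
        preds = reg.bpann_predict(model, scores)
        level_means = [preds[ds.levels == lv].mean() for lv in sorted(set(ds.levels))]
        rho, _ = spearmanr(sorted(set(ds.levels)), level_means)
        assert rho == pytest.approx(1.0)


class TestHiddenSelection:
    def test_singleton_grid_returns_five_for_nine_input_topology(self, rng):
        X = rng.uniform(size=(20, 9))
        y = rng.uniform(size=20)
        hyper = reg.BPANNHyperparams(max_epochs=100)
        best, trace = reg.bpann_select_hidden(X, y, X, y, [5], seed=0, hyper=hyper)
        assert best == 5 and len(trace) == 1  # topology 9−5−1

    def test_selection_reproducible_under_fixed_seed(self, rng):
        X = rng.uniform(size=(24, 3))
        y = X.mean(axis=1)
        hyper = reg.BPANNHyperparams(max_epochs=500)
        b1, t1 = reg.bpann_select_hidden(X, y, X, y, [2, 3, 5], seed=4, hyper=hyper)
        b2, t2 = reg.bpann_select_hidden(X, y, X, y, [2, 3, 5], seed=4, hyper=hyper)
        assert b1 == b2 and t1 == t2
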