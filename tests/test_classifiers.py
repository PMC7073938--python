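"""Fisher LDA and ELM: oracle equivalence, interpolation, tie rules."""

import numpy as np
import pytest
from scipy.special import expit

from chromanose import chemometrics, classifiers as clf, pipeline, synthgen
from chromanose.data import CLASS_ORDER, one_hot
from chromanose.errors import DomainError
from oracles import lda_axes_by_inversion


def _three_class_instance(rng, n_per_class=4, p=3, spread=3.0):
    X, labels = [], []
    for j, cls in enumerate(CLASS_ORDER):
        center = rng.normal(scale=spread, size=p)
        X.append(center + rng.normal(size=(n_per_class, p)))
        labels += [cls] * n_per_class
    return np.vstack(X), labels


class TestLDAFit:
    def test_df_count_bound_three_classes_nine_inputs(self, rng):
        X, labels = _three_class_instance(rng, n_per_class=6, p=9)
        model = clf.lda_fit(X, labels)
        assert model.s == 2  # min(k−1, p) with k = 3
        assert model.df_contribution.sum() == pytest.approx(1.0)

    def test_two_isotropic_clusters_axis_parallels_centroid_difference(self):
        # symmetric point clouds around each mean make Sw proportional to I
        offsets = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        m1, m2 = np.array([0.0, 0.0]), np.array([4.0, 2.0])
        X = np.vstack([m1 + offsets, m2 + offsets])
        labels = ["pure_beef"] * 4 + ["pure_pork"] * 4
        model = clf.lda_fit(X, labels)
        axis = model.df_coefficients[:, 0]
        direction = (m2 - m1) / np.linalg.norm(m2 - m1)
        assert abs(abs(axis @ direction) - 1.0) < 1e-10

    def test_axes_match_explicit_inversion_oracle(self, rng):
        for _ in range(10):
            X, labels = _three_class_instance(rng, n_per_class=4, p=3)
            model = clf.lda_fit(X, labels)
            evals, axes = lda_axes_by_inversion(X, labels, list(CLASS_ORDER))
            np.testing.assert_allclose(model.df_coefficients, axes, atol=1e-8)
            np.testing.assert_allclose(
                model.df_contribution, evals / evals.sum(), atol=1e-8
            )

    def test_singular_within_scatter_gets_ridge_with_warning(self):
        # duplicated rows per class: zero within-class scatter
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        labels = ["pure_beef", "pure_beef", "pure_pork", "pure_pork"]
        with pytest.warns(UserWarning, match="ridge"):
            model = clf.lda_fit(X, labels)
        assert model.s == 1

    def test_class_with_single_sample_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(DomainError):
            clf.lda_fit(X, ["pure_beef", "pure_beef", "pure_pork"])


class TestLDAPredict:
    def test_sample_at_centroid_and_tie_rule(self, rng):
        X, labels = _three_class_instance(rng, spread=6.0)
        model = clf.lda_fit(X, labels)
        # centroids project to themselves → assigned to their own class
        centroids_input = []
        for cls in model.class_order:
            centroids_input.append(X[[lab == cls for lab in labels]].mean(axis=0))
        preds = clf.lda_predict(model, np.vstack(centroids_input))
        assert preds == list(model.class_order)

    def test_equidistant_sample_goes_to_first_class_in_order(self):
        offsets = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        X = np.vstack([offsets - [2, 0], offsets + [2, 0]])
        labels = ["pure_beef"] * 4 + ["pure_pork"] * 4
        model = clf.lda_fit(X, labels)
        assert clf.lda_predict(model, [[0.0, 0.0]]) == ["pure_beef"]

    def test_perfect_rate_on_noiseless_synthetic_data(self, noiseless_model):
        # retain the level design's intrinsic dimensionality (6 levels → 5
        # components) so the noise-free classes are linearly separable
        ds = synthgen.generate_dataset(model=noiseless_model, seed=5)
        pca = chemometrics.pca_fit(ds.X)
        k = max(5, chemometrics.select_components(pca, 0.90))
        scores = chemometrics.pca_transform(pca, ds.X, k)
        model = clf.lda_fit(scores, ds.categories)
        assert clf.lda_predict(model, scores) == ds.categories


class TestELM:
    def test_seed_contract(self, rng):
        X = rng.normal(size=(10, 4))
        T = one_hot(["pure_beef", "mixture"] * 5)
        a = clf.elm_fit(X, T, L=6, seed=3)
        b = clf.elm_fit(X, T, L=6, seed=3)
        c = clf.elm_fit(X, T, L=6, seed=4)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        assert not np.array_equal(a.input_weights, c.input_weights)

    def test_interpolation_with_L_equal_n(self, rng):
        n = 9
        X = rng.uniform(size=(n, 3))
        labels = [CLASS_ORDER[i % 3] for i in range(n)]
        model = clf.elm_fit(X, one_hot(labels), L=n, seed=0)
        assert clf.elm_predict(model, X) == labels

    def test_training_residual_orthogonal_to_hidden_columns(self, rng):
        X = rng.normal(size=(12, 4))
        labels = [CLASS_ORDER[i % 3] for i in range(12)]
        T = one_hot(labels)
        model = clf.elm_fit(X, T, L=5, seed=1)
        H = expit(X @ model.input_weights.T + model.biases)
        resid = H @ model.output_weights - T
        assert np.abs(H.T @ resid).max() < 1e-6

    def test_permuting_samples_permutes_predictions(self, rng):
        X = rng.normal(size=(10, 3))
        labels = [CLASS_ORDER[i % 3] for i in range(10)]
        model = clf.elm_fit(X, one_hot(labels), L=7, seed=2)
        perm = rng.permutation(10)
        preds = clf.elm_predict(model, X)
        np.testing.assert_array_equal(
            np.array(preds)[perm], clf.elm_predict(model, X[perm])
        )

    def test_perfect_rate_on_noiseless_synthetic_data(self, noiseless_model):
        ds = synthgen.generate_dataset(model=noiseless_model, seed=5)
        pca = chemometrics.pca_fit(ds.X)
        k = max(5, chemometrics.select_components(pca, 0.90))
        scores = chemometrics.pca_transform(pca, ds.X, k)
        norm = chemometrics.minmax_fit(scores)
        Xn = chemometrics.minmax_apply(norm, scores)
        model = clf.elm_fit(Xn, one_hot(ds.categories), L=20, seed=0)
        assert clf.elm_predict(model, Xn) == ds.categories

    def test_select_hidden_singleton_grid(self, rng):
        X = rng.normal(size=(10, 3))
        labels = [CLASS_ORDER[i % 3] for i in range(10)]
        best, trace = clf.elm_select_hidden(X, labels, X, labels, [1], seed=0)
        assert best == 1 and len(trace) == 1

    def test_select_hidden_reproducible_and_traced(self, rng):
        X = rng.normal(size=(20, 4))
        labels = [CLASS_ORDER[i % 3] for i in range(20)]
        grid = [2, 5, 10, 15]
        b1, t1 = clf.elm_select_hidden(X, labels, X, labels, grid, seed=9)
        b2, t2 = clf.elm_select_hidden(X, labels, X, labels, grid, seed=9)
        assert b1 == b2 and t1 == t2 and [L for L, _ in t1] == grid


class TestELMBeatsLDAOnNonlinearStructure:
    def test_seed_averaged_prediction_rates(self):
        """The three categories lie on a curved one-dimensional manifold
        (level 0 → beef, interior → mixture, 1 → pork), which a nearest-
        centroid linear discriminant cannot carve as well as the nonlinear
        ELM; seed-averaged over 20 replicates."""
        lda_rates, elm_rates = [], []
        for seed in range(20):
            model = synthgen.DyeResponseModel.default(seed=seed)
            ds = synthgen.generate_dataset(model=model, seed=seed)
            pca = chemometrics.pca_fit(ds.X)
            k = chemometrics.select_components(pca, 0.90)
            scores = chemometrics.pca_transform(pca, ds.X, k)
            plan = pipeline.SplitPlan(stratify_by="category", seed=seed)
            train, pred = pipeline.split_dataset(ds, plan)
            idx = {sid: i for i, sid in enumerate(ds.sample_ids)}
            Xtr = scores[[idx[s] for s in train.sample_ids]]
            Xpr = scores[[idx[s] for s in pred.sample_ids]]
            lda = clf.lda_fit(Xtr, train.categories)
            hits = np.mean(
                np.array(clf.lda_predict(lda, Xpr)) == np.array(pred.categories)
            )
            lda_rates.append(100 * hits)
            norm = chemometrics.minmax_fit(Xtr)
            Xtr_n, Xpr_n = chemometrics.minmax_apply(norm, Xtr), chemometrics.minmax_apply(norm, Xpr)
            L, _ = clf.elm_select_hidden(
                Xtr_n, train.categories, Xpr_n, pred.categories,
                range(5, 41, 5), seed=seed,
            )
            elm = clf.elm_fit(Xtr_n, one_hot(train.categories), L, seed=seed)
            hits = np.mean(
                np.array(clf.elm_predict(elm, Xpr_n)) == np.array(pred.categories)
            )
            elm_rates.append(100 * hits)
        assert np.mean(elm_rates) >= np.mean(lda_rates)
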