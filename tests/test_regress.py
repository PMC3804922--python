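"""Ridge regression, incremental updates, evaluation metrics, cluster safety."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import echoforce as ef
from echoforce import sessions
from echoforce.errors import (InvalidInputError, InvalidParameterError,
                              NormalizationError)


class TestFitRidge:
    def test_scalar_closed_form(self):
        model = ef.fit_ridge([[1.0]], [[1.0]], lam=1.0)
        assert model.W[0, 0] == pytest.approx(0.5)
        assert ef.predict(model, [1.0])[0] == pytest.approx(0.5)

    def test_zero_targets_zero_weights(self, rng):
        X = rng.normal(size=(20, 5))
        model = ef.fit_ridge(X, np.zeros((20, 2)))
        np.testing.assert_array_equal(model.W, 0.0)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.linear_model import Ridge

        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 3))
        model = ef.fit_ridge(X, Y, lam=1.0)
        oracle = Ridge(alpha=1.0, fit_intercept=False).fit(X, Y)
        np.testing.assert_allclose(model.W, oracle.coef_.T, rtol=1e-8,
                                   atol=1e-10)

    def test_stored_inverse_is_exact(self, rng):
        X = rng.normal(size=(30, 6))
        model = ef.fit_ridge(X, rng.normal(size=(30, 1)), lam=2.0)
        G = X.T @ X + 2.0 * np.eye(6)
        np.testing.assert_allclose(model.A @ G, np.eye(6), atol=1e-10)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            ef.fit_ridge([[np.nan]], [[1.0]])
        with pytest.raises(InvalidParameterError):
            ef.fit_ridge([[1.0]], [[1.0]], lam=0.0)


class TestIncrementalUpdate:
    @pytest.mark.parametrize("trial", range(5))
    def test_stream_equals_batch(self, trial):
        rng = np.random.default_rng(trial)
        n, d, k = rng.integers(5, 40), rng.integers(2, 12), rng.integers(1, 4)
        X = rng.normal(size=(n, d))
        Y = rng.normal(size=(n, k))
        batch = ef.fit_ridge(X, Y)
        inc = ef.RidgeModel(d=int(d), k=int(k))
        for x, y in zip(X, Y):
            ef.update_incremental(inc, x, y)
        scale = np.abs(batch.W).max()
        np.testing.assert_allclose(inc.W, batch.W, atol=1e-6 * max(scale, 1))

    def test_zero_sample_is_a_no_op(self, rng):
        model = ef.fit_ridge(rng.normal(size=(10, 4)), rng.normal(size=(10, 2)))
        A0, B0 = model.A.copy(), model.B.copy()
        ef.update_incremental(model, np.zeros(4), rng.normal(size=2))
        np.testing.assert_array_equal(model.A, A0)
        np.testing.assert_array_equal(model.B, B0)

    def test_duplicate_sample_matches_direct_inverse(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=1)
        model = ef.RidgeModel(d=5, k=1)
        ef.update_incremental(model, x, y)
        ef.update_incremental(model, x, y)
        X = np.stack([x, x])
        direct = np.linalg.inv(X.T @ X + np.eye(5))
        np.testing.assert_allclose(model.A, direct, atol=1e-8)

    def test_order_invariance_of_weights(self, rng):
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 2))
        m1 = ef.RidgeModel(d=6, k=2)
        m2 = ef.RidgeModel(d=6, k=2)
        for i in range(30):
            ef.update_incremental(m1, X[i], Y[i])
        for i in rng.permutation(30):
            ef.update_incremental(m2, X[i], Y[i])
        np.testing.assert_allclose(m1.W, m2.W, atol=1e-6)

    def test_inverse_stays_symmetric_after_many_updates(self, rng):
        model = ef.RidgeModel(d=20, k=1)
        for _ in range(2500):
            ef.update_incremental(model, rng.normal(size=20),
                                  rng.normal(size=1))
        assert np.abs(model.A - model.A.T).max() < 1e-8

    def test_state_size_constant_in_samples_seen(self, rng):
        # O(d^2) space/update contract: state arrays never grow with n
        model = ef.RidgeModel(d=8, k=2)
        sizes = set()
        for _ in range(50):
            ef.update_incremental(model, rng.normal(size=8),
                                  rng.normal(size=2))
            sizes.add((model.A.shape, model.B.shape,
                       model.A.nbytes + model.B.nbytes))
        assert len(sizes) == 1

    def test_dimension_mismatch_rejected(self):
        model = ef.RidgeModel(d=4, k=1)
        with pytest.raises(InvalidInputError):
            ef.update_incremental(model, np.zeros(5), np.zeros(1))
        with pytest.raises(InvalidInputError):
            ef.update_incremental(model, np.zeros(4), np.zeros(3))


@given(st.integers(0, 10 ** 6))
def test_stream_equals_batch_property(seed):
    """Sherman-Morrison streaming reproduces the batch ridge solution."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 5)) * rng.uniform(0.1, 10)
    Y = rng.normal(size=(12, 2))
    batch = ef.fit_ridge(X, Y)
    inc = ef.RidgeModel(d=5, k=2)
    for x, y in zip(X, Y):
        ef.update_incremental(inc, x, y)
    np.testing.assert_allclose(inc.W, batch.W,
                               atol=1e-6 * max(np.abs(batch.W).max(), 1))


class TestPredict:
    def test_empty_model_predicts_zero(self):
        model = ef.RidgeModel(d=6, k=3)
        np.testing.assert_array_equal(ef.predict(model, np.ones(6)),
                                      np.zeros(3))

    def test_matrix_input(self, rng):
        model = ef.fit_ridge(rng.normal(size=(20, 4)), rng.normal(size=(20, 2)))
        V = rng.normal(size=(7, 4))
        np.testing.assert_allclose(ef.predict(model, V), V @ model.W)

    def test_dimension_mismatch_rejected(self):
        model = ef.RidgeModel(d=6, k=3)
        with pytest.raises(InvalidInputError):
            ef.predict(model, np.ones(5))


class TestNrmse:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.normal(size=50)
        assert ef.nrmse(y, y) == 0.0

    def test_constant_offset(self):
        truth = np.array([0.0, 1.0, 2.0, 4.0])  # range 4
        assert ef.nrmse(truth + 1.0, truth) == pytest.approx(0.25)

    def test_matches_naive_formula(self, rng):
        pred = rng.normal(size=200)
        truth = rng.normal(size=200)
        naive = np.sqrt(np.sum((pred - truth) ** 2) / 200) / (
            np.max(truth) - np.min(truth))
        assert ef.nrmse(pred, truth) == pytest.approx(naive, abs=1e-12)

    def test_zero_range_rejected(self):
        with pytest.raises(NormalizationError):
            ef.nrmse(np.arange(5.0), np.ones(5))


class TestCrossValidate:
    @staticmethod
    def _linear_data(rng, n=200, d=12, k=3):
        X = rng.normal(size=(n, d))
        W = rng.normal(size=(d, k))
        return X, X @ W

    def test_fixed_seed_reproducible(self, rng):
        X, Y = self._linear_data(rng)
        r1 = ef.cross_validate(X, Y, reps=5, seed=3)
        r2 = ef.cross_validate(X, Y, reps=5, seed=3)
        np.testing.assert_array_equal(r1.mean_nrmse, r2.mean_nrmse)

    def test_more_training_data_no_worse(self, rng):
        X, Y = self._linear_data(rng)
        Y = Y + rng.normal(scale=0.1, size=Y.shape)
        lo = ef.cross_validate(X, Y, train_frac=0.1, reps=20, seed=0)
        hi = ef.cross_validate(X, Y, train_frac=0.9, reps=20, seed=0)
        assert np.all(hi.mean_nrmse <= lo.mean_nrmse + 0.01)

    def test_degenerate_training_fraction_rejected(self, rng):
        X, Y = self._linear_data(rng, n=20)
        with pytest.raises(InvalidParameterError):
            ef.cross_validate(X, Y, train_frac=0.001)

    def test_noiseless_session_error_below_two_percent(self, noiseless_session):
        gr = noiseless_session["GR1"]
        report = ef.cross_validate(gr.X, gr.Y_force, train_frac=0.1, reps=10,
                                   seed=0)
        assert np.all(report.mean_nrmse < 0.02)


class TestEvaluateTransfer:
    def test_training_set_error_bounds_cv_error(self, rng):
        X = rng.normal(size=(100, 10))
        Y = X @ rng.normal(size=(10, 2)) + rng.normal(scale=0.3, size=(100, 2))
        self_rep = ef.evaluate_transfer(X, Y, X, Y)
        cv = ef.cross_validate(X, Y, train_frac=0.5, reps=20, seed=1)
        assert np.all(self_rep.mean_nrmse <= cv.mean_nrmse + 1e-12)


class TestSafetyMatrix:
    def test_hand_computed_example(self):
        clusters = ef.ClusterSet({
            "i": np.array([[0.0, 0.0], [0.0, 2.0]]),
            "j": np.array([[10.0, 0.0], [10.0, 2.0]]),
        })
        labels, S = ef.safety_matrix(clusters)
        i, j = labels.index("i"), labels.index("j")
        # sigma_i = (0, 1) with the n-1 convention; centroid distance 10
        assert S[i, j] == pytest.approx(np.sqrt(2) / 10, abs=1e-12)
        assert np.isnan(S[i, i]) and np.isnan(S[j, j])

    def test_asymmetric_by_definition(self):
        clusters = ef.ClusterSet({
            "tight": np.array([[0.0, 0.0], [0.1, 0.0]]),
            "wide": np.array([[5.0, 0.0], [9.0, 0.0]]),
        })
        labels, S = ef.safety_matrix(clusters)
        assert S[0, 1] != S[1, 0]

    def test_coincident_centroids_flagged_infinite(self):
        clusters = ef.ClusterSet({
            "a": np.array([[0.0, 1.0], [0.0, -1.0]]),
            "b": np.array([[1.0, 0.0], [-1.0, 0.0]]),
        })
        with pytest.warns(UserWarning, match="coincident"):
            _, S = ef.safety_matrix(clusters)
        assert np.isinf(S[0, 1])

    def test_synthetic_onoff_clusters_well_separated(self, noisy_session):
        clusters = sessions.build_onoff_clusters(noisy_session["OO1"])
        labels, S = ef.safety_matrix(clusters)
        off_diag = S[~np.isnan(S)]
        assert off_diag.max() < 0.1

    def test_too_few_clusters_rejected(self):
        with pytest.raises(InvalidInputError):
            ef.safety_matrix(ef.ClusterSet({"only": np.zeros((3, 2))}))
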