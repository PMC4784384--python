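import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsclassify import (
    MLPModel,
    init_model,
    mlp_ensemble_predict,
    mlp_forward,
    mse_objective,
    tansig,
    train_scg,
)
from gsclassify.discretize import ClassLabeling
from gsclassify.mlp import (
    _pack,
    _unpack,
    early_stopping_schedule,
    load_mlp,
    loss_and_grad,
    save_mlp,
)


def make_binary_labeling(labels):
    labels = np.asarray(labels, dtype=int)
    return ClassLabeling(
        scheme={"kind": "two_class", "tail": "upper", "p": 0.5},
        class_names=["other", "upper"],
        labels=labels,
        counts=[int((labels == 0).sum()), int((labels == 1).sum())],
        target_class=1,
        cut_values=[0.0],
    )


class TestTansig:
    def test_zero(self):
        assert tansig(0.0) == 0.0

    def test_hand_value(self):
        # 2 / (1 + e^-2) - 1 = 0.761594...
        assert tansig(1.0) == pytest.approx(0.761594, abs=1e-6)

    def test_odd_symmetry(self):
        assert tansig(-1.0) == pytest.approx(-0.761594, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-50, 50))
    def test_equals_explicit_formula_and_range(self, u):
        explicit = 2.0 / (1.0 + np.exp(-2.0 * u)) - 1.0
        assert tansig(u) == pytest.approx(explicit, abs=1e-12)
        assert -1.0 <= tansig(u) <= 1.0


class TestForward:
    def test_zero_weights(self):
        model = MLPModel(np.zeros((3, 4)), np.zeros(3), np.zeros((2, 3)), np.zeros(2))
        Z, C_hat = mlp_forward(model, np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_array_equal(Z, 0.0)
        np.testing.assert_array_equal(C_hat, 0.5)

    def test_hand_nested_tansig(self):
        model = MLPModel(np.array([[1.0]]), np.zeros(1), np.array([[1.0]]), np.zeros(1))
        Z, C_hat = mlp_forward(model, np.array([[1.0]]))
        assert Z[0, 0] == pytest.approx(0.761594, abs=1e-6)
        o = np.tanh(0.7615941559557649)
        assert C_hat[0, 0] == pytest.approx((o + 1) / 2, abs=1e-9)
        assert C_hat[0, 0] == pytest.approx(0.821, abs=1e-3)

    def test_matches_per_neuron_loop(self):
        rng = np.random.default_rng(3)
        p, M, S, n = 4, 3, 2, 5
        model = init_model(p, M, S, rng)
        X = rng.normal(size=(n, p))
        Z, C_hat = mlp_forward(model, X)
        for i in range(n):
            z = np.empty(M)
            for m in range(M):
                z[m] = np.tanh(model.b_in[m] + model.W_in[m] @ X[i])
            np.testing.assert_allclose(Z[:, i], z, atol=1e-12)
            for k in range(S):
                o = np.tanh(model.b_out[k] + model.W_out[k] @ z)
                assert C_hat[k, i] == pytest.approx((o + 1) / 2, abs=1e-12)

    def test_dimension_mismatch(self):
        model = MLPModel(np.zeros((2, 3)), np.zeros(2), np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            mlp_forward(model, np.zeros((1, 4)))

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(8)
        model = init_model(6, 4, 3, rng)
        _, C_hat = mlp_forward(model, rng.normal(size=(10, 6)) * 50)
        assert (C_hat >= 0).all() and (C_hat <= 1).all()


class TestMSE:
    def test_identity_zero(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert mse_objective(C, C) == 0.0

    def test_half_everywhere(self):
        C = np.array([[1, 0, 1], [0, 1, 0]])
        C_hat = np.full((2, 3), 0.5)
        assert mse_objective(C_hat, C) == pytest.approx(0.25, abs=1e-15)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        C = np.zeros((3, 8))
        C[rng.integers(0, 3, 8), np.arange(8)] = 1
        C_hat = rng.uniform(size=(3, 8))
        perm = [2, 0, 1]
        assert mse_objective(C_hat, C) == pytest.approx(
            mse_objective(C_hat[perm], C[perm]), abs=1e-15
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_objective(np.zeros((2, 3)), np.zeros((3, 2)))


class TestGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_backprop_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 6))
        M = int(rng.integers(1, 4))
        S = int(rng.integers(1, 4))
        n = int(rng.integers(2, 8))
        X = rng.normal(size=(n, p))
        C = np.zeros((S, n))
        C[rng.integers(0, S, n), np.arange(n)] = 1
        w = _pack(init_model(p, M, S, rng)) + rng.normal(scale=0.3, size=(M * p + M + S * M + S))
        loss, grad = loss_and_grad(w, X, C, p, M, S)
        eps = 1e-6
        for idx in rng.choice(w.size, size=min(12, w.size), replace=False):
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            fd = (loss_and_grad(wp, X, C, p, M, S)[0] - loss_and_grad(wm, X, C, p, M, S)[0]) / (2 * eps)
            denom = max(abs(fd), abs(grad[idx]), 1e-8)
            assert abs(fd - grad[idx]) / denom < 1e-6


class TestEarlyStopping:
    def test_injected_trace_contract(self):
        stop, best = early_stopping_schedule([0.5, 0.4, 0.45, 0.5], patience=1)
        assert stop == 4
        assert best == 2

    def test_monotone_series_never_stops_early(self):
        stop, best = early_stopping_schedule([0.5, 0.4, 0.3, 0.2], patience=0)
        assert (stop, best) == (4, 4)

    def test_plateau_counts_as_no_improvement(self):
        stop, best = early_stopping_schedule([0.5, 0.5, 0.5], patience=1)
        assert (stop, best) == (3, 1)


class TestTrainSCG:
    def _separable(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 2)) + np.c_[labels * 6.0, np.zeros(n)]
        C = np.zeros((2, n))
        C[labels, np.arange(n)] = 1
        return X, C, labels

    def test_separable_reaches_perfect_training_accuracy(self):
        X, C, labels = self._separable()
        model = init_model(2, 2, 2, np.random.default_rng(1))
        trained, trace = train_scg(model, X, C, X, C, max_epochs=500, patience=10**9)
        _, C_hat = mlp_forward(trained, X)
        assert (C_hat.argmax(axis=0) == labels).mean() == 1.0

    def test_training_mse_nonincreasing_over_accepted_steps(self):
        X, C, _ = self._separable()
        model = init_model(2, 2, 2, np.random.default_rng(2))
        _, trace = train_scg(model, X, C, X, C, max_epochs=200, patience=10**9)
        mses = np.array(trace.train_mse)
        assert (np.diff(mses) <= 1e-12).all()

    def test_returns_best_validation_weights(self):
        rng = np.random.default_rng(3)
        X, C, _ = self._separable(seed=3)
        Xv = rng.normal(size=(10, 2))
        Cv = np.zeros((2, 10))
        Cv[rng.integers(0, 2, 10), np.arange(10)] = 1
        model = init_model(2, 3, 2, rng)
        trained, trace = train_scg(model, X, C, Xv, Cv, max_epochs=100, patience=3)
        _, C_hat_val = mlp_forward(trained, Xv)
        returned_val = float(np.mean((C_hat_val - Cv) ** 2))
        assert returned_val == pytest.approx(min(trace.val_mse), abs=1e-12)
        assert trace.best_iteration <= trace.stop_iteration

    def test_same_seed_identical(self):
        X, C, _ = self._separable()
        m1 = init_model(2, 2, 2, np.random.default_rng(7))
        m2 = init_model(2, 2, 2, np.random.default_rng(7))
        t1, tr1 = train_scg(m1, X, C, X, C, max_epochs=50, patience=5)
        t2, tr2 = train_scg(m2, X, C, X, C, max_epochs=50, patience=5)
        np.testing.assert_array_equal(t1.W_in, t2.W_in)
        assert tr1.val_mse == tr2.val_mse

    def test_empty_validation_rejected(self):
        X, C, _ = self._separable()
        model = init_model(2, 2, 2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="validation"):
            train_scg(model, X, C, np.empty((0, 2)), np.empty((2, 0)), max_epochs=5)


class TestArchitecture:
    def test_hidden_size_zero_disallowed(self):
        with pytest.raises(ValueError):
            init_model(4, 0, 2, np.random.default_rng(0))

    def test_label_swap_swaps_score_rows(self):
        rng = np.random.default_rng(5)
        model = init_model(3, 2, 2, rng)
        swapped = MLPModel(model.W_in, model.b_in, model.W_out[::-1].copy(), model.b_out[::-1].copy())
        X = rng.normal(size=(6, 3))
        _, C1 = mlp_forward(model, X)
        _, C2 = mlp_forward(swapped, X)
        np.testing.assert_allclose(C1, C2[::-1], atol=1e-15)

    def test_pack_unpack_roundtrip(self):
        model = init_model(5, 3, 2, np.random.default_rng(1))
        back = _unpack(_pack(model), 5, 3, 2)
        np.testing.assert_array_equal(back.W_in, model.W_in)
        np.testing.assert_array_equal(back.b_out, model.b_out)


class TestEnsemble:
    def _data(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 3)) + np.c_[labels * 3.0, np.zeros(n), np.zeros(n)]
        C = np.zeros((2, n))
        C[labels, np.arange(n)] = 1
        return X, C, make_binary_labeling(labels)

    def test_single_replicate_runs(self):
        X, C, lab = self._data()
        scores = mlp_ensemble_predict(X, C, lab, X[:10], M_grid=[2], replicates=1,
                                      seed=0, max_epochs=50)
        assert scores.shape == (2, 10)

    def test_mean_of_identical_scores_is_identity(self):
        rng = np.random.default_rng(0)
        stack = np.repeat(rng.uniform(size=(1, 2, 5)), 4, axis=0)
        np.testing.assert_allclose(stack.mean(axis=0), stack[0])

    def test_per_replicate_mean_equals_scores_aggregate(self):
        X, C, lab = self._data()
        per = mlp_ensemble_predict(X, C, lab, X[:8], M_grid=[1, 2], replicates=3,
                                   seed=5, max_epochs=40, aggregate="per_replicate")
        mean = mlp_ensemble_predict(X, C, lab, X[:8], M_grid=[1, 2], replicates=3,
                                    seed=5, max_epochs=40, aggregate="scores")
        assert per.shape == (3, 2, 8)
        np.testing.assert_allclose(per.mean(axis=0), mean, atol=1e-12)

    def test_deterministic_given_seed(self):
        X, C, lab = self._data()
        s1 = mlp_ensemble_predict(X, C, lab, X[:5], M_grid=[1], replicates=2, seed=3, max_epochs=30)
        s2 = mlp_ensemble_predict(X, C, lab, X[:5], M_grid=[1], replicates=2, seed=3, max_epochs=30)
        np.testing.assert_array_equal(s1, s2)

    def test_ensemble_auc_not_worse_than_single_mean(self):
        """Variance-reduction check on a Gaussian-mixture benchmark."""
        from gsclassify import roc_auc

        rng = np.random.default_rng(42)
        n = 400
        labels = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 2))
        X[:, 0] += labels * 2.0
        C = np.zeros((2, n))
        C[labels, np.arange(n)] = 1
        lab = make_binary_labeling(labels)
        te_labels = rng.integers(0, 2, size=200)
        Xte = rng.normal(size=(200, 2))
        Xte[:, 0] += te_labels * 2.0
        per = mlp_ensemble_predict(X, C, lab, Xte, M_grid=[2], replicates=10,
                                   seed=1, max_epochs=100, aggregate="per_replicate")
        single_aucs = [roc_auc(per[r, 1], te_labels == 1).area for r in range(10)]
        ens_auc = roc_auc(per.mean(axis=0)[1], te_labels == 1).area
        assert ens_auc >= np.mean(single_aucs) - 0.02


class TestPersistence:
    def test_save_load_identity(self, tmp_path):
        model = init_model(4, 3, 2, np.random.default_rng(9))
        save_mlp(model, tmp_path / "mlp")
        back = load_mlp(tmp_path / "mlp")
        for a, b in ((back.W_in, model.W_in), (back.b_in, model.b_in),
                     (back.W_out, model.W_out), (back.b_out, model.b_out)):
            np.testing.assert_array_equal(a, b)
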