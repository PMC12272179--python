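"""Model zoo: forward contracts, oracle equivalences, training, iteration."""

import numpy as np
import pytest

from neuroar.cohort import make_coupling, simulate_run
from neuroar.errors import ContractError, DivergenceError
from neuroar.graphs import random_connectome, scaled_laplacian
from neuroar.models import (ModelConfig, build_model, chebnet_forward,
                            chebyshev_basis_apply, count_parameters, fit,
                            fit_direct_multilag, forward, grid_search,
                            predict_iterated)
from neuroar.preprocess import make_windows, zscore_per_run


class TestForward:
    def test_linear_uni_scalar(self):
        m = build_model(ModelConfig("linear_uni", k=1, bias=False), 1)
        m.params["W0"] = np.array([[0.5]])
        assert forward(m, np.array([[[2.0]]]))[0, 0] == pytest.approx(1.0)

    def test_linear_multi_persistence(self, rng):
        P, k = 4, 3
        m = build_model(ModelConfig("linear_multi", k=k, bias=False), P)
        W = np.zeros((k * P, P))
        W[(k - 1) * P:, :] = np.eye(P)  # select the window's last row
        m.params["W0"] = W
        win = rng.standard_normal((5, k, P))
        np.testing.assert_allclose(forward(m, win), win[:, -1, :])

    @pytest.mark.parametrize("family", ["mlp_uni", "mlp_multi"])
    def test_linear_mlp_collapses_to_matrix_product(self, rng, family):
        P, k = 3, 2
        cfg = ModelConfig(family, k=k, hidden_sizes=(5, 4), nonlinear=False, bias=False)
        m = build_model(cfg, P)
        win = rng.standard_normal((6, k, P))
        out = forward(m, win)
        if family == "mlp_multi":
            op = m.params["W0"] @ m.params["W1"] @ m.params["W2"]
            expected = win.reshape(6, -1) @ op
        else:
            expected = np.empty((6, P))
            for j in range(P):
                op = m.params["W0"][j] @ m.params["W1"][j] @ m.params["W2"][j]
                expected[:, j] = win[:, :, j] @ op[:, 0]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_shape_contract(self, rng):
        m = build_model(ModelConfig("linear_uni", k=2), 3)
        with pytest.raises(ContractError):
            forward(m, rng.standard_normal((5, 4, 3)))


class TestChebyshevBasis:
    def test_low_orders_are_identity_and_laplacian(self, small_spectral_op, rng):
        x = rng.standard_normal((6, 2))
        terms = chebyshev_basis_apply(small_spectral_op, x, 2)
        np.testing.assert_allclose(terms[0], x)
        np.testing.assert_allclose(terms[1], small_spectral_op.scaled_laplacian @ x)

    def test_recurrence_matches_spectral_evaluation(self, small_spectral_op, rng):
        # independent oracle: evaluate T_k on the eigenvalues and rotate back
        x = rng.standard_normal((6, 3))
        K = 4
        terms = chebyshev_basis_apply(small_spectral_op, x, K)
        lam, U = np.linalg.eigh(small_spectral_op.scaled_laplacian)
        for j in range(K):
            Tj = np.cos(j * np.arccos(np.clip(lam, -1, 1)))
            dense = U @ (Tj[:, None] * (U.T @ x))
            np.testing.assert_allclose(terms[j], dense, atol=1e-8)


class TestChebnetForward:
    def test_identity_configuration(self, small_spectral_op):
        m = build_model(ModelConfig("chebnet", k=1, cheb_order=1, bias=False,
                                    nonlinear=False), 6, small_spectral_op)
        m.params["theta0"] = np.ones((1, 1, 1))
        win = np.arange(6, dtype=float).reshape(1, 1, 6)
        np.testing.assert_allclose(chebnet_forward(m, win)[0], win[0, 0])

    def test_linear_chebnet_equals_assembled_operator(self, small_spectral_op, rng):
        P, k, K = 6, 3, 3
        cfg = ModelConfig("chebnet", k=k, cheb_order=K, hidden_sizes=(4,),
                          nonlinear=False)
        m = build_model(cfg, P, small_spectral_op)
        win = rng.standard_normal((5, k, P))
        Lt = small_spectral_op.scaled_laplacian
        Ts = [np.eye(P), Lt, 2 * Lt @ Lt - np.eye(P)]

        def layer(X, theta, b):
            return sum(Ts[j] @ X @ theta[j] for j in range(K)) + b

        expected = np.empty((5, P))
        for n in range(5):
            h = layer(win[n].T, m.params["theta0"], m.params["b0"])
            expected[n] = layer(h, m.params["theta1"], m.params["b1"])[:, 0]
        np.testing.assert_allclose(forward(m, win), expected, atol=1e-6)

    def test_edgeless_graph_keeps_nodes_independent(self, rng):
        P = 5
        from neuroar.graphs import Connectome
        with pytest.warns(UserWarning):
            sop = scaled_laplacian(Connectome(
                adjacency=np.zeros((P, P), dtype=np.uint8), density=0.0, kind="random"))
        m = build_model(ModelConfig("chebnet", k=2, cheb_order=3, hidden_sizes=(4,)),
                        P, sop)
        win = rng.standard_normal((1, 2, P))
        base = forward(m, win)
        bumped = win.copy()
        bumped[0, :, 2] += 1.0
        out = forward(m, bumped)
        changed = np.abs(out - base)[0]
        assert changed[2] > 0
        np.testing.assert_allclose(np.delete(changed, 2), 0, atol=1e-12)

    def test_missing_spectral_op_rejected(self):
        with pytest.raises(ContractError):
            build_model(ModelConfig("chebnet", k=1), 4)


class TestCountParameters:
    @pytest.mark.parametrize("family,k,P,expected", [
        ("linear_uni", 256, 197, 197 * (256 + 1)),   # 50,629 ~ 5e4
        ("linear_multi", 3, 197, 197 * (3 * 197 + 1)),  # 116,624 ~ 1e5
        ("linear_uni", 1, 1, 2),
    ])
    def test_linear_counts(self, family, k, P, expected):
        m = build_model(ModelConfig(family, k=k, bias=True), P)
        assert count_parameters(m) == expected

    def test_chebnet_count_formula(self, small_spectral_op):
        cfg = ModelConfig("chebnet", k=4, cheb_order=3, hidden_sizes=(8,))
        m = build_model(cfg, 6, small_spectral_op)
        assert count_parameters(m) == 3 * 4 * 8 + 8 + 3 * 8 * 1 + 1


class TestFit:
    def test_bitwise_deterministic(self, rng):
        data = rng.standard_normal((80, 3))
        from conftest import make_series
        ws = make_windows([make_series(data)], 2, 1)
        runs = []
        for _ in range(2):
            m = build_model(ModelConfig("mlp_multi", k=2, hidden_sizes=(4,), seed=3), 3)
            m = fit(m, ws, epochs=5, batch_size=16, learning_rate=0.01, seed=7)
            runs.append({k: v.copy() for k, v in m.params.items()})
        for key in runs[0]:
            np.testing.assert_array_equal(runs[0][key], runs[1][key])

    def test_recovers_scalar_ar1_weight(self):
        couplings = np.array([[[0.5]]])
        ts = simulate_run(couplings, None, 1.0, 4000, seed=1)
        ws = make_windows([ts], 1, 1)
        m = build_model(ModelConfig("linear_uni", k=1, bias=False, seed=0), 1)
        m = fit(m, ws, epochs=60, batch_size=256, learning_rate=0.02, seed=0)
        assert m.params["W0"][0, 0] == pytest.approx(0.5, abs=0.01)

    def test_training_loss_non_increasing_full_batch(self, rng):
        from conftest import make_series
        ws = make_windows([make_series(rng.standard_normal((120, 2)))], 1, 1)
        m = build_model(ModelConfig("linear_multi", k=1, seed=0), 2)
        m = fit(m, ws, epochs=30, batch_size=ws.n_samples, learning_rate=1e-3, seed=0)
        losses = [h["train_loss"] for h in m.training_history]
        diffs = np.diff(losses)
        assert np.all(diffs <= 1e-6)

    def test_nonfinite_loss_raises_divergence(self, rng):
        from conftest import make_series
        ws = make_windows([make_series(rng.standard_normal((60, 3)))], 1, 1)
        m = build_model(ModelConfig("linear_multi", k=1, seed=0), 3)
        m.params["W0"] = np.full((3, 3), 1e200)  # forward overflows -> loss = inf
        with pytest.raises(DivergenceError) as err:
            fit(m, ws, epochs=3, batch_size=16, learning_rate=1e-2, seed=0)
        assert err.value.epoch == 0


class TestPredictIterated:
    def test_scalar_closed_form(self):
        from conftest import make_series
        m = build_model(ModelConfig("linear_uni", k=1, bias=False), 1)
        m.params["W0"] = np.array([[0.5]])
        ts = make_series(np.ones((10, 1)))
        it = predict_iterated(m, ts, 3)
        _, pred3, _ = it.aligned(3)
        np.testing.assert_allclose(pred3, 0.125)

    def test_lag1_equals_forward(self, var1_system, var1_runs):
        couplings, _ = var1_system
        _, test = var1_runs
        m = build_model(ModelConfig("linear_multi", k=1, bias=False), 10)
        m.params["W0"] = couplings[0].T.copy()
        it = predict_iterated(m, test[0], 3)
        ws = make_windows([test[0]], 1, 1)
        np.testing.assert_array_equal(it.aligned(1)[1], forward(m, ws.inputs))

    def test_matrix_power_oracle(self, var1_system, var1_runs):
        couplings, _ = var1_system
        _, test = var1_runs
        A = couplings[0]
        m = build_model(ModelConfig("linear_multi", k=1, bias=False), 10)
        m.params["W0"] = A.T.copy()
        it = predict_iterated(m, test[0], 4)
        X = test[0].data
        for lag in (1, 2, 3, 4):
            _, pred, _ = it.aligned(lag)
            expected = (np.linalg.matrix_power(A, lag) @ X[:pred.shape[0]].T).T
            np.testing.assert_allclose(pred, expected, atol=1e-8)

    def test_short_series_rejected(self, rng):
        from conftest import make_series
        m = build_model(ModelConfig("linear_uni", k=4), 2)
        with pytest.raises(ContractError):
            predict_iterated(m, make_series(rng.standard_normal((6, 2))), 3)


class TestGridSearch:
    def _data(self, seed=0):
        couplings, _ = make_coupling(6, 0.4, 1, 0.8, seed=seed)
        train = [zscore_per_run(simulate_run(couplings, None, 1.0, 300,
                                             seed=seed * 10 + r, run=f"run-{r}"))
                 for r in range(2)]
        val = [zscore_per_run(simulate_run(couplings, None, 1.0, 300,
                                           seed=seed * 10 + 5, run="run-v"))]
        return {"sub-01": (train, val)}

    def test_singleton_grid(self):
        cfg = ModelConfig("linear_multi", k=1)
        best, table = grid_search([cfg], self._data(), [1], epochs=3)
        assert best is cfg and len(table) == 1

    def test_tie_returns_first(self):
        cfg = ModelConfig("linear_multi", k=1)
        best, _ = grid_search([cfg, ModelConfig("linear_multi", k=1)], self._data(),
                              [1], epochs=3)
        assert best is cfg

    def test_generating_family_preferred(self):
        # multivariate VAR data: the multivariate linear model should beat
        # the univariate one in most replicates
        wins = 0
        for seed in range(5):
            grid = [ModelConfig("linear_uni", k=1), ModelConfig("linear_multi", k=1)]
            best, _ = grid_search(grid, self._data(seed), [1], epochs=25,
                                  learning_rate=0.02, batch_size=256)
            wins += best.family == "linear_multi"
        assert wins >= 4


class TestDirectMultilag:
    def test_reduces_to_fit_at_single_lag(self, var1_runs):
        train, _ = var1_runs
        cfg = ModelConfig("linear_multi", k=1, seed=0)
        ws = make_windows(train, 1, 1)
        direct = fit_direct_multilag(cfg, {1: (ws, None)}, 10, epochs=4, seed=0)
        single = fit(build_model(cfg, 10), ws, epochs=4, seed=0)
        np.testing.assert_array_equal(direct[1].params["W0"], single.params["W0"])

    def test_models_trained_independently(self, var1_runs):
        train, _ = var1_runs
        cfg = ModelConfig("linear_multi", k=1, seed=0)
        by_lag = {lag: (make_windows(train, 1, lag), None) for lag in (1, 2)}
        a = fit_direct_multilag(cfg, by_lag, 10, epochs=3, seed=0)
        b = fit_direct_multilag(cfg, dict(reversed(list(by_lag.items()))), 10,
                                epochs=3, seed=0)
        for lag in (1, 2):
            np.testing.assert_array_equal(a[lag].params["W0"], b[lag].params["W0"])

    def test_direct_lag2_competitive_with_iterated(self, var1_system):
        # direct lag-2 training should not trail iterated lag-2 by much
        from neuroar.evaluation import r2_score
        couplings, _ = var1_system
        gaps = []
        for seed in range(5):
            train = [simulate_run(couplings, None, 1.0, 1500, seed=300 + seed)]
            test = simulate_run(couplings, None, 1.0, 600, seed=400 + seed)
            cfg = ModelConfig("linear_multi", k=1, seed=0)
            m1 = fit(build_model(cfg, 10), make_windows(train, 1, 1),
                     epochs=40, batch_size=256, learning_rate=0.02, seed=0)
            m2 = fit(build_model(cfg, 10), make_windows(train, 1, 2),
                     epochs=40, batch_size=256, learning_rate=0.02, seed=0)
            it = predict_iterated(m1, test, 2)
            _, pred_it, truth = it.aligned(2)
            ws2 = make_windows([test], 1, 2)
            pred_dir = forward(m2, ws2.inputs)
            r2_it = r2_score(truth, pred_it).mean()
            r2_dir = r2_score(ws2.targets, pred_dir).mean()
            gaps.append(r2_dir - r2_it)
        assert np.median(gaps) >= -0.05


class TestChebnetCeiling:
    def test_reaches_theoretical_ceiling_on_graph_var(self):
        # generator coupling is a polynomial of the graph Laplacian, so the
        # Chebnet with the true graph can represent the optimal predictor
        from neuroar.cohort import _rescale_to_radius
        from neuroar.evaluation import evaluate_model
        P = 12
        sop = scaled_laplacian(random_connectome(P, 0.3, seed=4))
        Lt = sop.scaled_laplacian
        Apoly = 0.6 * np.eye(P) + 0.3 * Lt + 0.15 * (2 * Lt @ Lt - np.eye(P))
        A = _rescale_to_radius(Apoly[None, ...], 0.85)
        train = simulate_run(A, None, 1.0, 5000, seed=5)
        test = simulate_run(A, None, 1.0, 3000, seed=6)
        m = build_model(ModelConfig("chebnet", k=1, cheb_order=3, nonlinear=False,
                                    seed=0), P, sop)
        m = fit(m, make_windows([train], 1, 1), epochs=60, batch_size=512,
                learning_rate=0.02, seed=0)
        r2 = np.mean([r.r2_mean for r in evaluate_model(m, [test], [1])])
        ceiling = float((1 - 1.0 / test.data.var(axis=0)).mean())
        assert r2 >= ceiling - 0.05
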