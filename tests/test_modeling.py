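import numpy as np
import pandas as pd
import pytest

from phenoliq.modeling import (
    AnnSearchSpace,
    fit_ols,
    predict_linear,
    sensitivity_ranking,
    train_ann,
    train_ann_ensemble,
)

from oracles import ols_normal_equations


def linear_data(seed=0, n=30, p=4, beta=None, sigma=0.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.arange(1, p + 1, dtype=float) if beta is None else np.asarray(beta)
    y = X @ beta + rng.normal(0, sigma, n)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(p)]), y


class TestOls:
    def test_exact_single_column(self):
        X, _ = linear_data(seed=1, sigma=0.0, p=1, beta=[1.0])
        y = X["x0"].to_numpy()
        model = fit_ols(X, y, standardize=True)
        assert model.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(model.residuals, 0.0, atol=1e-10)

    def test_noiseless_recovery_raw_scale(self):
        X, y = linear_data(seed=2, sigma=0.0, beta=[2.0, -1.0, 0.5, 3.0])
        model = fit_ols(X, y, standardize=False)
        np.testing.assert_allclose(model.coef, [2.0, -1.0, 0.5, 3.0], atol=1e-10)
        np.testing.assert_allclose(model.intercept, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        for seed in range(10):
            X, y = linear_data(seed=seed, sigma=0.7)
            model = fit_ols(X, y, standardize=False)
            beta, se, t = ols_normal_equations(X.to_numpy(), y)
            np.testing.assert_allclose(model.intercept, beta[0], rtol=1e-10)
            np.testing.assert_allclose(model.coef, beta[1:], rtol=1e-10)
            np.testing.assert_allclose(model.se, se[1:], rtol=1e-10)
            np.testing.assert_allclose(model.t_values, t[1:], rtol=1e-10)

    def test_monte_carlo_coefficient_bias(self):
        beta = np.array([1.0, -2.0, 0.5, 1.5])
        estimates = []
        for seed in range(500):
            X, y = linear_data(seed=seed, sigma=1.0, beta=beta)
            model = fit_ols(X, y, standardize=False)
            estimates.append(model.coef)
        estimates = np.asarray(estimates)
        bias = estimates.mean(axis=0) - beta
        sem = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert np.all(np.abs(bias) < 2 * sem + 1e-12)

    def test_rank_deficiency_names_columns(self):
        X, y = linear_data(seed=3)
        X["x0_clone"] = X["x0"]
        with pytest.raises(ValueError, match="x0"):
            fit_ols(X, y)

    def test_r2_identity(self):
        X, y = linear_data(seed=4, sigma=1.0)
        model = fit_ols(X, y)
        sse = float(np.sum(model.residuals**2))
        sst = float(np.sum((y - y.mean()) ** 2))
        assert model.r2 == pytest.approx(1 - sse / sst, abs=1e-12)


class TestPredictLinear:
    def test_training_rows_reproduce_fitted(self):
        X, y = linear_data(seed=5, sigma=0.4)
        model = fit_ols(X, y, standardize=True)
        np.testing.assert_allclose(model.predict(X), model.fitted, atol=1e-10)

    def test_row_at_training_means_gives_intercept(self):
        X, y = linear_data(seed=6, sigma=0.4)
        model = fit_ols(X, y, standardize=True)
        at_mean = pd.DataFrame([X.mean()], columns=X.columns)
        assert model.predict(at_mean)[0] == pytest.approx(model.intercept)

    def test_hand_computed_two_descriptor_prediction(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.0, 1.0, 0.0, 1.0]})
        y = np.array([1.0, 4.0, 3.0, 6.0])  # y = a + 2b exactly
        model = fit_ols(X, y, standardize=False)
        new = pd.DataFrame({"a": [10.0], "b": [3.0]})
        assert model.predict(new)[0] == pytest.approx(16.0, abs=1e-9)

    def test_missing_column_rejected(self):
        X, y = linear_data(seed=7)
        model = fit_ols(X, y)
        with pytest.raises(KeyError):
            predict_linear(model, X[["x0", "x1"]])


class TestAnn:
    def test_linear_limit_matches_ols(self):
        X, y = linear_data(seed=8, n=39, sigma=0.3)
        train_idx = np.arange(0, 30)
        test_idx = np.arange(30, 39)
        net = train_ann(
            X, y, train_idx, test_idx,
            n_hidden=4, hidden_activation="identity", output_activation="identity",
            hidden_decay=0.0, output_decay=0.0, seed=0, max_iter=2000,
            early_stopping=False,
        )
        ols = fit_ols(X.iloc[train_idx], y[train_idx], standardize=True)
        rmse = np.sqrt(np.mean((net.predict(X) - ols.predict(X)) ** 2))
        assert rmse < 1e-3

    def test_constant_response_learned(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = np.full(20, 4.2)
        net = train_ann(X, y, np.arange(15), np.arange(15, 20),
                        n_hidden=3, seed=1, max_iter=200)
        np.testing.assert_allclose(net.predict(X), 4.2, atol=1e-6)

    def test_early_stopping_best_not_worse_than_final(self):
        X, y = linear_data(seed=10, n=25, p=3, sigma=1.5)
        net = train_ann(X, y, np.arange(18), np.arange(18, 25),
                        n_hidden=8, hidden_activation="tanh",
                        output_activation="identity", seed=3, max_iter=400)
        test_errs = [h[2] for h in net.history]
        assert test_errs[net.best_iteration] <= test_errs[-1] + 1e-15

    def test_decay_shrinks_weights(self):
        X, y = linear_data(seed=11, n=30, p=3, sigma=0.3)
        norms = []
        for decay in (0.0, 0.1, 10.0, 1000.0):
            net = train_ann(X, y, np.arange(24), np.arange(24, 30),
                            n_hidden=4, seed=5, max_iter=300,
                            hidden_decay=decay, output_decay=decay,
                            early_stopping=False)
            norms.append(np.sqrt(np.sum(net.w1**2) + np.sum(net.w2**2)))
        assert norms[-1] < norms[1] < norms[0] + 1e-9
        assert norms[-1] < 0.05 * norms[0]

    def test_serialization_round_trip(self, tmp_path):
        X, y = linear_data(seed=12, n=25, p=3)
        net = train_ann(X, y, np.arange(20), np.arange(20, 25), n_hidden=3, seed=2,
                        max_iter=100)
        path = tmp_path / "net.json"
        net.to_json(path)
        from phenoliq.modeling import NeuralNetModel

        loaded = NeuralNetModel.from_json(path)
        np.testing.assert_allclose(loaded.predict(X), net.predict(X), atol=1e-12)

    def test_stored_errors_recompute_from_weights(self):
        X, y = linear_data(seed=13, n=25, p=3)
        train_idx, test_idx = np.arange(20), np.arange(20, 25)
        net = train_ann(X, y, train_idx, test_idx, n_hidden=3, seed=4, max_iter=150)
        # recompute the best-iteration test error from the stored weights
        ys = net.y_lo + (y - net.y_min) / net.y_range * (net.y_hi - net.y_lo)
        pred_scaled = net.y_lo + (net.predict(X) - net.y_min) / net.y_range * (net.y_hi - net.y_lo)
        recomputed = float(np.mean((pred_scaled[test_idx] - ys[test_idx]) ** 2))
        assert recomputed == pytest.approx(net.history[net.best_iteration][2], abs=1e-12)


@pytest.fixture(scope="module")
def small_problem():
    X, y = linear_data(seed=20, n=39, p=4, sigma=0.4)
    split = np.array(["train"] * 25 + ["test"] * 5 + ["validation"] * 9)
    return X, y, split


class TestAnnEnsemble:
    def test_fixed_seed_reproducible(self, small_problem):
        X, y, split = small_problem
        space = AnnSearchSpace(max_iter=60)
        _, board_a = train_ann_ensemble(X, y, split, space, n_networks=6, seed=42)
        _, board_b = train_ann_ensemble(X, y, split, space, n_networks=6, seed=42)
        pd.testing.assert_frame_equal(board_a, board_b)

    def test_leaderboard_and_selection(self, small_problem):
        X, y, split = small_problem
        space = AnnSearchSpace(max_iter=60)
        best, board = train_ann_ensemble(X, y, split, space, n_networks=6, seed=1)
        assert len(board) == 6
        assert board["n_hidden"].between(3, 8).all()
        assert best is not None

    def test_empty_test_subset_rejected(self, small_problem):
        X, y, _ = small_problem
        split = np.array(["train"] * 30 + ["validation"] * 9)
        with pytest.raises(ValueError, match="test"):
            train_ann_ensemble(X, y, split, n_networks=2, seed=0)


class TestSensitivityRanking:
    def test_ignored_input_ranked_last_with_unit_ratio(self):
        X, y = linear_data(seed=30, n=30, p=3, sigma=0.2)
        net = train_ann(X, y, np.arange(24), np.arange(24, 30), n_hidden=3,
                        hidden_activation="identity", output_activation="identity",
                        seed=7, max_iter=200, early_stopping=False)
        net.w1[:, 2] = 0.0  # sever input x2
        ranking = sensitivity_ranking(net, X, y)
        assert ranking.iloc[-1]["descriptor"] == "x2"
        assert ranking.iloc[-1]["ratio"] == pytest.approx(1.0, abs=1e-12)

    def test_magnitude_order_for_linear_network(self):
        # |beta| = (3, 1, 0.5) on uncorrelated standardized inputs
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=["a", "b", "c"])
        X = (X - X.mean()) / X.std(ddof=1)
        y = (3.0 * X["a"] + 1.0 * X["b"] + 0.5 * X["c"]).to_numpy()
        net = train_ann(X, y, np.arange(160), np.arange(160, 200), n_hidden=3,
                        hidden_activation="identity", output_activation="identity",
                        hidden_decay=0.0, output_decay=0.0,
                        seed=8, max_iter=1000, early_stopping=False)
        ranking = sensitivity_ranking(net, X, y)
        assert ranking["descriptor"].tolist() == ["a", "b", "c"]
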