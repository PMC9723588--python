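"""Surface models: pair construction, GBT/RF/FFNN/polynomial contracts."""

import logging

import numpy as np
import pandas as pd
import pytest

from lakebrowning.errors import (
    DegenerateGradientError,
    InvalidHyperparameterError,
    SplitError,
    ZeroVarianceError,
)
from lakebrowning.surface import (
    PairDataset,
    build_pair_dataset,
    evaluate_model,
    fit_ffnn,
    fit_gradient_boost,
    fit_polynomial,
    fit_random_forest,
    predict_meshgrid,
    select_degree,
    split_train_test,
    _RegressionTree,
)


def toy_pairs(n_sites=12, seed=0, fn=None):
    rng = np.random.default_rng(seed)
    g = np.sort(rng.uniform(0, 10, n_sites))
    d = np.zeros((n_sites, n_sites))
    fn = fn or (lambda a, b: np.clip(0.1 + 0.08 * abs(a - b), 0, 1))
    for i in range(n_sites):
        for j in range(n_sites):
            if i != j:
                d[i, j] = fn(g[i], g[j])
    d = (d + d.T) / 2
    return g, build_pair_dataset(g, d)


class TestPairDataset:
    def test_symmetric_counts(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.abs(g[:, None] - g[None, :]) / 10
        assert len(build_pair_dataset(g, d, symmetric=True)) == 12
        assert len(build_pair_dataset(g, d, symmetric=False)) == 6

    def test_mirrored_rows_carry_equal_distance(self):
        g, pairs = toy_pairs()
        f = pairs.frame
        merged = f.merge(f, left_on=["i", "j"], right_on=["j", "i"])
        assert np.allclose(merged["d_x"], merged["d_y"])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            build_pair_dataset(np.arange(3.0), np.zeros((4, 4)))


class TestSplit:
    def test_sizes_and_partition(self):
        g, pairs = toy_pairs(16)  # 120 unordered pairs
        train, test = split_train_test(pairs, 0.8, seed=1)
        n_pairs = pairs.frame["pair_key"].nunique()
        n_test = test.frame["pair_key"].nunique()
        assert abs(n_test - 0.2 * n_pairs) <= 1
        assert len(train) + len(test) == len(pairs)
        assert not (set(train.frame["pair_key"]) & set(test.frame["pair_key"]))

    def test_mirrored_rows_stay_in_same_fold(self):
        g, pairs = toy_pairs(10)
        train, test = split_train_test(pairs, 0.8, seed=3)
        for fold in (train, test):
            counts = fold.frame.groupby("pair_key").size()
            assert (counts == 2).all()

    def test_same_seed_same_split(self):
        g, pairs = toy_pairs(10)
        a, _ = split_train_test(pairs, 0.8, seed=7)
        b, _ = split_train_test(pairs, 0.8, seed=7)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_too_few_rows(self):
        frame = pd.DataFrame({"i": [0], "j": [1], "g1": [0.0], "g2": [1.0],
                              "d": [0.5], "pair_key": [1]})
        with pytest.raises(SplitError):
            split_train_test(PairDataset(frame, False), 0.8, 0)


class TestGradientBoost:
    def test_zero_rounds_predicts_training_mean(self):
        g, pairs = toy_pairs()
        model = fit_gradient_boost(pairs, rounds=0)
        pred = model.predict(np.array([[0.0, 1.0], [9.0, 2.0]]))
        assert np.allclose(pred, pairs.y.mean())

    def test_training_mse_non_increasing_every_round(self):
        g, pairs = toy_pairs(14, seed=2)
        model = fit_gradient_boost(pairs, rounds=80)
        assert np.all(np.diff(model.train_history) <= 1e-12)

    def test_exact_fit_of_blockwise_target(self):
        # piecewise-constant noiseless target with <= 2^depth blocks, full
        # shrinkage, no regularization: training MSE reaches ~0 quickly.
        # (The blocks must not form an XOR layout — a zero first-order gain
        # at the root stops any gain-guided greedy tree.)
        g = np.array([1.0, 2.0, 6.0, 7.0])
        levels = {(0, 0): 0.1, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 0.9}
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i != j:
                    d[i, j] = levels[(int(g[i] > 4), int(g[j] > 4))]
        pairs = build_pair_dataset(g, d)
        model = fit_gradient_boost(pairs, rounds=20, depth=2,
                                   learning_rate=1.0, reg_lambda=0.0)
        assert model.train_history[-1] < 1e-20

    def test_stump_split_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.normal(size=(40, 2))
            y = rng.normal(size=40)
            tree = _RegressionTree(max_depth=1, reg_lambda=0.0).fit(x, y)
            best_sse, best = np.inf, None
            for f in range(2):
                for thr in np.unique(x[:, f])[:-1]:
                    mask = x[:, f] <= thr
                    if not mask.any() or mask.all():
                        continue
                    sse = (((y[mask] - y[mask].mean()) ** 2).sum()
                           + ((y[~mask] - y[~mask].mean()) ** 2).sum())
                    if sse < best_sse - 1e-12:
                        best_sse, best = sse, f
            node = tree.root
            mask = x[:, node.feature] <= node.threshold
            sse = (((y[mask] - y[mask].mean()) ** 2).sum()
                   + ((y[~mask] - y[~mask].mean()) ** 2).sum())
            assert sse == pytest.approx(best_sse, abs=1e-9)

    def test_invalid_learning_rate(self):
        g, pairs = toy_pairs()
        with pytest.raises(InvalidHyperparameterError):
            fit_gradient_boost(pairs, learning_rate=0.0)

    def test_matches_xgboost_reference(self):
        # same loss, exact greedy splits, same lambda: predictions should
        # agree closely with the reference boosted-tree implementation
        import xgboost as xgb

        g, pairs = toy_pairs(15, seed=4)
        ours = fit_gradient_boost(pairs, rounds=40, depth=3,
                                  learning_rate=0.3, reg_lambda=1.0)
        ref = xgb.XGBRegressor(
            n_estimators=40, max_depth=3, learning_rate=0.3, reg_lambda=1.0,
            base_score=float(pairs.y.mean()), tree_method="exact",
            min_child_weight=0, gamma=0,
        ).fit(pairs.x, pairs.y)
        pred_ours = ours.predict(pairs.x)
        pred_ref = ref.predict(pairs.x)
        assert np.corrcoef(pred_ours, pred_ref)[0, 1] > 0.999
        assert np.max(np.abs(pred_ours - pred_ref)) < 0.02

    def test_symmetric_surface_on_standard_scenario(self, standard_surface):
        s = standard_surface["mesh"].values
        srange = s.max() - s.min()
        assert np.max(np.abs(s - s.T)) <= 0.05 * srange


class TestRandomForest:
    def test_constant_target_constant_prediction(self):
        g, pairs = toy_pairs(fn=lambda a, b: 0.4)
        model = fit_random_forest(pairs, n_trees=10, seed=0)
        assert np.allclose(model.predict(np.array([[1.0, 2.0]])), 0.4)

    def test_prediction_is_mean_of_trees(self, rng):
        g, pairs = toy_pairs(12, seed=5)
        model = fit_random_forest(pairs, n_trees=25, seed=1)
        queries = rng.uniform(0, 10, size=(50, 2))
        per_tree = np.vstack([t.predict(queries) for t in model.estimators_])
        assert np.allclose(model.predict(queries), per_tree.mean(axis=0),
                           atol=1e-12)

    def test_same_seed_identical_forest(self, rng):
        g, pairs = toy_pairs(10, seed=6)
        q = rng.uniform(0, 10, size=(20, 2))
        a = fit_random_forest(pairs, n_trees=15, seed=9).predict(q)
        b = fit_random_forest(pairs, n_trees=15, seed=9).predict(q)
        assert np.array_equal(a, b)


class TestFfnn:
    def test_xavier_bounds_hold_for_every_layer(self):
        g, pairs = toy_pairs()
        model = fit_ffnn(pairs, hidden_layers=(16, 16), epochs=1, seed=0)
        sizes = [2, 16, 16, 1]
        init = type(model.network)(sizes, seed=0)
        for w, (fi, fo) in zip(init.weights, zip(sizes[:-1], sizes[1:])):
            bound = np.sqrt(6.0 / (fi + fo))
            assert np.abs(w).max() <= bound

    def test_training_reduces_loss_on_toy_problem(self):
        g, pairs = toy_pairs(14, seed=7)
        model = fit_ffnn(pairs, hidden_layers=(16,), epochs=200,
                         learning_rate=0.01, seed=1)
        assert model.train_history[-1] < model.train_history[0]

    def test_linear_network_approaches_ols(self):
        g, pairs = toy_pairs(14, seed=8)
        model = fit_ffnn(pairs, hidden_layers=(), epochs=800,
                         learning_rate=0.05, batch_size=len(pairs), seed=2)
        x = np.column_stack([np.ones(len(pairs)), pairs.x])
        coef, *_ = np.linalg.lstsq(x, pairs.y, rcond=None)
        ols_mse = float(((x @ coef - pairs.y) ** 2).mean())
        assert model.train_history[-1] <= ols_mse * 1.05 + 1e-12


class TestPolynomial:
    def test_degree_zero_is_mean(self):
        g, pairs = toy_pairs()
        model = fit_polynomial(pairs, 0)
        assert np.allclose(model.predict(np.array([[3.0, 4.0]])), pairs.y.mean())

    def test_exact_linear_target_zero_residuals(self):
        g, pairs = toy_pairs(fn=lambda a, b: 0.1 + 0.02 * a + 0.03 * b)
        model = fit_polynomial(pairs, 1)
        assert np.allclose(model.predict(pairs.x), pairs.y, atol=1e-9)

    def test_matches_normal_equations(self):
        g, pairs = toy_pairs(14, seed=9)
        model = fit_polynomial(pairs, 2)
        from lakebrowning.surface import _poly_design

        design = _poly_design(pairs.x, 2)
        coef = np.linalg.solve(design.T @ design, design.T @ pairs.y)
        assert np.allclose(model.coef_, coef, atol=1e-8)


class TestSelectDegree:
    def test_noiseless_linear_chooses_degree_one(self):
        g, pairs = toy_pairs(14, fn=lambda a, b: 0.1 + 0.02 * a + 0.02 * b)
        sel = select_degree(pairs, degrees=range(1, 5), n_resamples=10, seed=0)
        assert sel.chosen == 1

    def test_error_decomposition_identity(self):
        g, pairs = toy_pairs(14, seed=10)
        sel = select_degree(pairs, degrees=range(0, 4), n_resamples=15, seed=1)
        for e, v, b in zip(sel.error, sel.variance, sel.bias_sq_plus_noise):
            assert e == pytest.approx(v + b, rel=1e-9)

    def test_cubic_surface_recovers_moderate_degree(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = np.sort(rng.uniform(0, 4, 14))
            d = np.zeros((14, 14))
            for i in range(14):
                for j in range(14):
                    if i != j:
                        s = g[i] + g[j]
                        d[i, j] = 0.02 * s**3 - 0.15 * s**2 + 0.3 * s + 0.3
            d = np.clip((d + d.T) / 2 + rng.normal(0, 0.05, (14, 14)), 0, None)
            np.fill_diagonal(d, 0)
            d = (d + d.T) / 2
            pairs = build_pair_dataset(g, d)
            sel = select_degree(pairs, degrees=range(0, 7),
                                n_resamples=20, seed=seed)
            hits += 2 <= sel.chosen <= 5
        assert hits >= 18


class TestMeshgrid:
    def test_step_is_smallest_pairwise_difference(self):
        g, pairs = toy_pairs(4)
        model = fit_polynomial(pairs, 0)
        mesh = predict_meshgrid(model, np.array([1.0, 2.0, 4.0]))
        assert mesh.step == pytest.approx(1.0)
        assert np.allclose(mesh.axis, [1, 2, 3, 4])

    def test_constant_model_baseline(self):
        g, pairs = toy_pairs(fn=lambda a, b: 0.37)
        model = fit_polynomial(pairs, 0)
        mesh = predict_meshgrid(model, g)
        assert np.allclose(mesh.values, 0.37)
        assert mesh.baseline == pytest.approx(0.37)

    def test_axis_capped_with_log_message(self, caplog):
        g = np.array([0.0, 1e-5, 10.0])
        _, pairs = toy_pairs(4)
        model = fit_polynomial(pairs, 0)
        with caplog.at_level(logging.INFO, logger="lakebrowning.surface"):
            mesh = predict_meshgrid(model, g, max_grid=100)
        assert len(mesh.axis) == 100
        assert any("inflated" in r.message for r in caplog.records)

    def test_degenerate_gradient(self):
        g, pairs = toy_pairs(4)
        model = fit_polynomial(pairs, 0)
        with pytest.raises(DegenerateGradientError):
            predict_meshgrid(model, np.full(5, 2.0))


class TestEvaluate:
    def test_perfect_predictions(self):
        g, pairs = toy_pairs(fn=lambda a, b: 0.1 + 0.02 * a + 0.03 * b)
        train, test = split_train_test(pairs, 0.8, 0)
        model = fit_polynomial(train, 1)
        fit = evaluate_model(model, test)
        assert fit.test_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.test_mse == pytest.approx(0.0, abs=1e-12)

    def test_mean_predictor_r2_zero_on_train(self):
        g, pairs = toy_pairs(12, seed=11)
        model = fit_polynomial(pairs, 0)
        fit = evaluate_model(model, pairs)
        assert fit.train_r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        # y = (.1,.2,.3,.4,.5), pred = (.12,.18,.33,.38,.52):
        # SS_res = 0.0025, SS_tot = 0.1 -> R^2 = 0.975, MSE = 0.0005
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        pred = np.array([0.12, 0.18, 0.33, 0.38, 0.52])
        frame = pd.DataFrame({"i": 0, "j": 1, "g1": np.arange(5.0),
                              "g2": np.arange(5.0), "d": y, "pair_key": 0})
        test = PairDataset(frame, False)

        class Fixed:
            train_x = frame[["g1", "g2"]].to_numpy()
            train_y = pred

            @staticmethod
            def predict(x):
                return pred[:len(x)]

        fit = evaluate_model(Fixed(), test)
        assert fit.test_mse == pytest.approx(0.0005)
        assert fit.test_r2 == pytest.approx(0.975)

    def test_zero_variance_targets_raise_with_mse(self):
        frame = pd.DataFrame({"i": 0, "j": 1, "g1": np.arange(5.0),
                              "g2": np.arange(5.0), "d": 0.5, "pair_key": 0})
        test = PairDataset(frame, False)

        class Fixed:
            train_x = frame[["g1", "g2"]].to_numpy()
            train_y = np.arange(5.0)

            @staticmethod
            def predict(x):
                return np.full(len(x), 0.4)

        with pytest.raises(ZeroVarianceError) as err:
            evaluate_model(Fixed(), test)
        assert err.value.mse == pytest.approx(0.01)
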