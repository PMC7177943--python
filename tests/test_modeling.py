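"""Stepwise selection, NIPALS PLS, metrics and cross-validation, checked
against OLS normal equations, scikit-learn's PLS, brute-force minimizers and
naive refit loops."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import koffgrid as kg
from koffgrid.modeling import _folds


def make_data(n, p, beta_map, sigma, seed, n_train=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    cols = [f"x{j}" for j in range(p)]
    y = np.zeros(n)
    for j, b in beta_map.items():
        y += b * X[:, j]
    y += sigma * rng.standard_normal(n)
    split = None
    if n_train is not None:
        labels = np.array(["validation"] * n, dtype=object)
        labels[:n_train] = "train"
        split = labels
    return kg.ModelingDataset.from_arrays(X, y, split=split, columns=cols)


class TestSMR:
    def test_recovers_planted_pair_and_matches_exhaustive_search(self):
        data = make_data(60, 40, {17: 2.0, 33: -1.0}, sigma=0.1, seed=0)
        selected = kg.smr_select(data, max_vars=2)
        assert set(selected[:2]) == {"x17", "x33"}
        # exhaustive 2-subset OLS search oracle
        X = data.X.to_numpy()
        y = data.y.to_numpy()
        best, best_sse = None, np.inf
        for a in range(40):
            for b in range(a + 1, 40):
                Z = np.column_stack([np.ones(60), X[:, a], X[:, b]])
                r = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
                sse = r @ r
                if sse < best_sse:
                    best, best_sse = {f"x{a}", f"x{b}"}, sse
        assert set(selected[:2]) == best

    def test_pure_noise_terminates_with_valid_entry_pvalues(self):
        data = make_data(60, 80, {}, sigma=1.0, seed=1)
        selected = kg.smr_select(data, max_vars=9)
        assert len(selected) <= 9  # terminates under the cap

    def test_duplicate_column_is_never_coselected(self):
        data = make_data(50, 10, {3: 2.0}, sigma=0.1, seed=2)
        X = data.X.copy()
        X["x3_dup"] = X["x3"] + 1e-9 * np.random.default_rng(3).standard_normal(50)
        dup = kg.ModelingDataset(X, data.y, data.split)
        selected = kg.smr_select(dup, max_vars=5)
        assert not {"x3", "x3_dup"}.issubset(set(selected))

    def test_constant_column_excluded_with_warning(self):
        data = make_data(30, 5, {1: 1.0}, sigma=0.1, seed=4)
        X = data.X.copy()
        X["x0"] = 1.234
        const = kg.ModelingDataset(X, data.y, data.split)
        with pytest.warns(UserWarning, match="constant"):
            selected = kg.smr_select(const, max_vars=3)
        assert "x0" not in selected

    def test_too_few_rows_rejected(self):
        data = make_data(3, 5, {1: 1.0}, sigma=0.1, seed=5)
        with pytest.raises(ValueError, match="few training rows"):
            kg.smr_select(data)


class TestPLS:
    def test_univariate_pls_equals_simple_ols(self):
        data = make_data(25, 1, {0: 1.5}, sigma=0.2, seed=6)
        model = kg.pls_fit(data, ["x0"], 1)
        x = data.X["x0"].to_numpy()
        y = data.y.to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(
            kg.pls_predict(model, data.X).to_numpy(), slope * x + intercept, atol=1e-10
        )

    def test_full_rank_pls_equals_ols_normal_equations(self):
        data = make_data(30, 4, {0: 1.0, 1: 2.0, 2: -1.0}, sigma=0.1, seed=7)
        model = kg.pls_fit(data, list(data.X.columns), 4)
        Z = np.column_stack([np.ones(30), data.X.to_numpy()])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ data.y.to_numpy())
        np.testing.assert_allclose(
            kg.pls_predict(model, data.X).to_numpy(), Z @ beta, atol=1e-8
        )

    def test_scores_are_orthogonal_and_reconstruction_holds(self):
        data = make_data(40, 6, {0: 1.0, 3: -2.0}, sigma=0.3, seed=8)
        model = kg.pls_fit(data, list(data.X.columns), 3)
        gram = model.T.T @ model.T
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        Xs = (data.X.to_numpy() - model.x_mean) / model.x_scale
        np.testing.assert_allclose(model.T @ model.P.T + model.E, Xs, atol=1e-8)

    def test_matches_sklearn_pls_predictions(self):
        data = make_data(35, 5, {0: 1.0, 2: 1.0}, sigma=0.2, seed=9)
        for ncomp in (1, 2, 3):
            model = kg.pls_fit(data, list(data.X.columns), ncomp)
            sk = PLSRegression(n_components=ncomp, scale=True).fit(
                data.X.to_numpy(), data.y.to_numpy()
            )
            np.testing.assert_allclose(
                kg.pls_predict(model, data.X).to_numpy(),
                sk.predict(data.X.to_numpy()).ravel(),
                atol=1e-8,
            )

    def test_ncomp_beyond_rank_rejected(self):
        data = make_data(20, 3, {0: 1.0}, sigma=0.1, seed=10)
        X = data.X.copy()
        X["x2"] = X["x0"] + X["x1"]  # rank 2 after scaling
        sing = kg.ModelingDataset(X, data.y, data.split)
        with pytest.raises(ValueError, match="rank"):
            kg.pls_fit(sing, list(X.columns), 3)

    def test_predict_names_missing_columns_and_handles_empty(self):
        data = make_data(20, 2, {0: 1.0}, sigma=0.1, seed=11)
        model = kg.pls_fit(data, ["x0", "x1"], 1)
        with pytest.raises(KeyError, match="x1"):
            kg.pls_predict(model, data.X[["x0"]])
        empty = kg.pls_predict(model, data.X.iloc[:0])
        assert len(empty) == 0

    def test_shifting_a_predictor_shifts_predictions_linearly(self):
        data = make_data(25, 3, {1: 2.0}, sigma=0.1, seed=12)
        model = kg.pls_fit(data, list(data.X.columns), 2)
        shifted = data.X.copy()
        shifted["x1"] = shifted["x1"] + 1.0
        delta = kg.pls_predict(model, shifted) - kg.pls_predict(model, data.X)
        coef = model.coef_[model.var_names.index("x1")]
        np.testing.assert_allclose(delta.to_numpy(), coef, atol=1e-10)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        data = make_data(20, 3, {0: 1.0}, sigma=0.1, seed=13)
        model = kg.pls_fit(data, list(data.X.columns), 2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = kg.PLSModel.from_json(path)
        np.testing.assert_allclose(
            kg.pls_predict(back, data.X).to_numpy(),
            kg.pls_predict(model, data.X).to_numpy(),
        )


class TestMetrics:
    def test_rmse_hand_values(self):
        assert kg.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert kg.rmse([2.0, 3.0], [1.0, 2.0]) == 1.0
        assert kg.rmse([1.0, 3.0], [2.0, 5.0]) == pytest.approx(np.sqrt((1 + 4) / 2))
        with pytest.raises(ValueError):
            kg.rmse([1.0], [1.0, 2.0])

    def test_mape_hand_values(self):
        assert kg.mape([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert kg.mape([1.0, 3.0], [2.0, 4.0]) == pytest.approx(0.375)
        with pytest.raises(ValueError):
            kg.mape([1.0], [0.0])

    def test_through_origin_slope_identity_scaling_and_bruteforce(self):
        rng = np.random.default_rng(14)
        y = rng.standard_normal(30)
        assert kg.through_origin_slope(y, y) == pytest.approx(1.0)
        assert kg.through_origin_slope(2 * y, y) == pytest.approx(2.0)
        yhat = y + 0.3 * rng.standard_normal(30)
        b = kg.through_origin_slope(y, yhat)
        grid = np.linspace(b - 1, b + 1, 2_000_001)
        sse = ((y[:, None] - grid[None, :] * yhat[:, None]) ** 2).sum(axis=0)
        assert b == pytest.approx(grid[np.argmin(sse)], abs=1e-6)
        with pytest.raises(ValueError):
            kg.through_origin_slope(y, np.zeros(30))

    def test_metrics_invariant_to_row_order(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal(20)
        yhat = y + 0.2 * rng.standard_normal(20)
        perm = rng.permutation(20)
        assert kg.rmse(yhat, y) == pytest.approx(kg.rmse(yhat[perm], y[perm]))
        assert kg.through_origin_slope(y, yhat) == pytest.approx(
            kg.through_origin_slope(y[perm], yhat[perm])
        )


class TestCrossValidation:
    def test_loo_equals_naive_refit_loop(self):
        data = make_data(15, 3, {0: 1.0, 1: -0.5}, sigma=0.2, seed=16)
        variables = list(data.X.columns)
        got = kg.q2_cv(data, variables, 2, scheme="LOO")
        y = data.y.to_numpy()
        press = 0.0
        for i in range(15):
            mask = np.ones(15, dtype=bool)
            mask[i] = False
            sub = kg.ModelingDataset.from_arrays(
                data.X.iloc[mask].to_numpy(), y[mask], columns=variables
            )
            model = kg.pls_fit(sub, variables, 2)
            pred = kg.pls_predict(model, data.X.iloc[[i]]).iloc[0]
            press += (y[i] - pred) ** 2
        want = 1 - press / ((y - y.mean()) ** 2).sum()
        assert got == want  # identical arithmetic path

    def test_noise_free_linear_data_has_q2_of_one(self):
        data = make_data(20, 2, {0: 1.0, 1: 2.0}, sigma=0.0, seed=17)
        assert kg.q2_cv(data, ["x0", "x1"], 2, scheme="LOO") == pytest.approx(1.0, abs=1e-10)

    def test_permuted_response_scores_poorly(self):
        data = make_data(60, 3, {0: 2.0}, sigma=0.1, seed=18)
        y_perm = data.y.sample(frac=1.0, random_state=0).to_numpy()
        perm = kg.ModelingDataset(data.X, pd.Series(y_perm, index=data.X.index), data.split)
        assert kg.q2_cv(perm, ["x0", "x1", "x2"], 2, scheme="5-fold", seed=0) < 0.2

    def test_folds_partition_and_seeded_reproducibility(self):
        f1 = _folds(23, "5-fold", seed=4)
        f2 = _folds(23, "5-fold", seed=4)
        assert sorted(np.concatenate(f1).tolist()) == list(range(23))
        assert all((a == b).all() for a, b in zip(f1, f2))
        with pytest.raises(ValueError, match="scheme"):
            _folds(10, "2-fold", seed=0)


class TestSelectModel:
    def test_nested_report_shape_and_planted_choice(self):
        data = make_data(60, 20, {4: 2.0, 9: -1.0}, sigma=0.3, seed=19, n_train=40)
        sequence = kg.smr_select(data, max_vars=6)
        sel = kg.select_model(data, sequence, scheme="5-fold", seed=0)
        assert len(sel.report) == len(sequence)  # one row per nested model
        assert set(sel.model.var_names) == {"x4", "x9"}
        chosen = sel.report.iloc[sel.chosen]
        assert chosen["selected"]
        assert chosen["R2"] >= chosen["Q2"] - 0.05

    def test_single_candidate_returned_unconditionally(self):
        data = make_data(30, 3, {0: 1.0}, sigma=0.2, seed=20, n_train=20)
        sel = kg.select_model(data, ["x0"], ncomp_grid=(1,), scheme="LOO")
        assert sel.model.var_names == ["x0"]
        assert len(sel.report) == 1

    def test_empty_candidate_list_rejected(self):
        data = make_data(20, 2, {0: 1.0}, sigma=0.1, seed=21)
        with pytest.raises(ValueError, match="candidate"):
            kg.select_model(data, [])
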