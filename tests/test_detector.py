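"""Cost-weighted boosting, grid-search selection rule and importances."""

import numpy as np
import pandas as pd
import pytest

from focalwear.dataset import FEATURE_NAMES, NormalizationParams, zscore_fit
from focalwear.detector import (
    GTBMParams,
    grid_search,
    importance,
    load_bundle,
    predict,
    reduced_param_grid,
    save_bundle,
    train,
)


def _norm_for(X: pd.DataFrame) -> NormalizationParams:
    return NormalizationParams(
        feature_names=tuple(X.columns),
        center=np.zeros(X.shape[1]),
        scale=np.ones(X.shape[1]),
    )


def _frame(arr):
    arr = np.asarray(arr, dtype=float)
    if arr.shape[1] < 11:
        arr = np.hstack([arr, np.zeros((arr.shape[0], 11 - arr.shape[1]))])
        # pad columns get tiny noise so they are not constant
        rng = np.random.default_rng(0)
        arr[:, 2:] += rng.normal(scale=1e-3, size=(arr.shape[0], 9))
    return pd.DataFrame(arr, columns=list(FEATURE_NAMES))


@pytest.fixture
def separable():
    rng = np.random.default_rng(5)
    X0 = rng.normal(loc=-2.0, size=(60, 2))
    X1 = rng.normal(loc=+2.0, size=(40, 2))
    X = _frame(np.vstack([X0, X1]))
    y = np.array([0] * 60 + [1] * 40)
    return X, y


class TestTrainPredict:
    def test_separable_zero_training_error(self, separable):
        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(max_depth=2, n_learners=20),
                       _norm_for(X), seed=0)
        pred = predict(bundle, X)
        np.testing.assert_array_equal(pred, y)

    def test_single_class_rejected(self, separable):
        X, _ = separable
        with pytest.raises(ValueError):
            train(X.to_numpy(), np.zeros(X.shape[0], dtype=int), GTBMParams(), _norm_for(X))

    def test_fp_cost_monotone_on_training_fp(self):
        rng = np.random.default_rng(9)
        X = _frame(rng.normal(size=(400, 2)))
        # noisy labels correlated with feature 0
        y = (X.iloc[:, 0].to_numpy() + rng.normal(scale=1.5, size=400) > 0).astype(int)
        fps = []
        for cost in (1.0, 5.0, 20.0, 50.0):
            b = train(X.to_numpy(), y, GTBMParams(fp_cost=cost, n_learners=30, max_depth=1),
                      _norm_for(X), seed=3)
            pred = predict(b, X)
            fps.append(int(((pred == 1) & (y == 0)).sum()))
        assert all(a >= b for a, b in zip(fps, fps[1:]))

    def test_single_stump_matches_exhaustive_search(self):
        """n_learners=1, max_depth=1 must equal the best cost-weighted stump
        found by brute force over every (feature, threshold) split by
        weighted Gini impurity."""
        rng = np.random.default_rng(21)
        X = _frame(rng.normal(size=(80, 2)))
        y = (X.iloc[:, 0].to_numpy() + 0.5 * rng.normal(size=80) > 0).astype(int)
        params = GTBMParams(n_learners=1, max_depth=1, fp_cost=5.0)
        bundle = train(X.to_numpy(), y, params, _norm_for(X), seed=0)
        pred = predict(bundle, X)

        w = np.where(y == 0, params.fp_cost, 1.0)

        def weighted_gini(mask):
            out = 0.0
            for side in (mask, ~mask):
                ws = w[side].sum()
                if ws == 0:
                    continue
                p1 = w[side][y[side] == 1].sum() / ws
                out += ws * 2 * p1 * (1 - p1)
            return out

        best = (np.inf, None)
        for j in range(11):
            xs = np.sort(np.unique(X.iloc[:, j].to_numpy()))
            for thr in (xs[1:] + xs[:-1]) / 2:
                mask = X.iloc[:, j].to_numpy() <= thr
                g = weighted_gini(mask)
                if g < best[0]:
                    left1 = w[mask][y[mask] == 1].sum() > w[mask][y[mask] == 0].sum()
                    right1 = w[~mask][y[~mask] == 1].sum() > w[~mask][y[~mask] == 0].sum()
                    oracle = np.where(mask, int(left1), int(right1))
                    best = (g, oracle)
        np.testing.assert_array_equal(pred, best[1])

    def test_deterministic_given_seed(self, separable):
        X, y = separable
        p1 = predict(train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=7), X)
        p2 = predict(train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=7), X)
        np.testing.assert_array_equal(p1, p2)

    def test_column_order_irrelevant(self, separable):
        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=0)
        shuffled = X[list(X.columns[::-1])]
        np.testing.assert_array_equal(predict(bundle, X), predict(bundle, shuffled))

    def test_missing_feature_errors(self, separable):
        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=0)
        with pytest.raises(KeyError):
            predict(bundle, X.drop(columns=["f_acc_det"]))

    def test_all_masked_rows_predict_zero(self, separable):
        from focalwear.dataset import FeatureGrid

        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=0)
        grid = FeatureGrid(
            participant_id="m",
            grid_times=np.arange(X.shape[0]) * 2.0,
            features=X,
            valid=pd.DataFrame(False, index=X.index, columns=X.columns),
        )
        assert predict(bundle, grid).sum() == 0


class TestGridSearch:
    def _eval_table(self, table):
        def eval_fn(params, fold):
            return table[params][fold]

        return eval_fn

    def test_sensitivity_first(self):
        grid = [GTBMParams(0.1, 50, 1, 1.0), GTBMParams(0.2, 50, 1, 1.0)]
        table = {grid[0]: [(1.0, 10)], grid[1]: [(0.5, 0)]}
        best, _ = grid_search([0], grid, self._eval_table(table))
        assert best == grid[0]

    def test_fp_breaks_sensitivity_tie(self):
        grid = [GTBMParams(0.1, 50, 1, 1.0), GTBMParams(0.1, 100, 1, 1.0)]
        table = {grid[0]: [(1.0, 7)], grid[1]: [(1.0, 3)]}
        best, _ = grid_search([0], grid, self._eval_table(table))
        assert best == grid[1]

    def test_learning_rate_breaks_full_tie(self):
        grid = [GTBMParams(0.1, 50, 1, 1.0), GTBMParams(0.5, 50, 1, 1.0)]
        table = {g: [(1.0, 3)] for g in grid}
        best, _ = grid_search([0], grid, self._eval_table(table))
        assert best.learning_rate == 0.5

    def test_fewer_learners_breaks_remaining_tie(self):
        grid = [GTBMParams(0.5, 200, 1, 1.0), GTBMParams(0.5, 50, 1, 1.0)]
        table = {g: [(1.0, 3)] for g in grid}
        best, _ = grid_search([0], grid, self._eval_table(table))
        assert best.n_learners == 50

    def test_unique_winner_on_random_tables(self, rng):
        grid = reduced_param_grid()
        table = {g: [(float(rng.choice([0.5, 1.0])), float(rng.integers(0, 5)))] for g in grid}
        best1, _ = grid_search([0], grid, self._eval_table(table))
        best2, _ = grid_search([0], list(reversed(grid)),
                               self._eval_table(table))
        assert best1 == best2  # total order: winner independent of grid order

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([0], [], lambda p, f: (0, 0))


class TestImportance:
    def test_single_stump_mass_on_split_feature(self, separable):
        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(n_learners=1, max_depth=1),
                       _norm_for(X), seed=0)
        scores = importance(bundle)
        assert scores.min() >= 0
        assert scores.idxmax() in ("f_acc_det", "f_acc_entr")
        assert scores.drop(scores.idxmax()).max() == 0

    def test_planted_eda_signal_recovered(self, rng):
        n = 600
        X = pd.DataFrame(rng.normal(size=(n, 11)), columns=list(FEATURE_NAMES))
        y = (X["f_eda_dmax"] + X["f_eda_dauc"] > 0).astype(int).to_numpy()
        bundle = train(X.to_numpy(), y, GTBMParams(n_learners=50, max_depth=2),
                       _norm_for(X), seed=0)
        s = importance(bundle)
        eda = s[["f_eda_dauc", "f_eda_dmax", "f_eda_dscrr"]].mean()
        acc = s[["f_acc_det", "f_acc_entr", "f_acc_len", "f_acc_rr"]].mean()
        bvp = s[["f_bvp_dmaxhr", "f_bvp_dmeanhr", "f_bvp_sqi", "f_bvp_hr"]].mean()
        assert eda > acc and eda > bvp

    def test_average_over_bundles(self, separable):
        X, y = separable
        b1 = train(X.to_numpy(), y, GTBMParams(n_learners=5), _norm_for(X), seed=0)
        b2 = train(X.to_numpy(), y, GTBMParams(n_learners=5), _norm_for(X), seed=1)
        merged = importance([b1, b2])
        np.testing.assert_allclose(
            merged.to_numpy(), (importance(b1) + importance(b2)).to_numpy() / 2
        )


class TestPersistence:
    def test_round_trip(self, tmp_path, separable):
        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=0)
        save_bundle(tmp_path / "b", bundle)
        back = load_bundle(tmp_path / "b")
        np.testing.assert_array_equal(predict(back, X), predict(bundle, X))
        assert back.params == bundle.params

    def test_schema_mismatch_refused(self, tmp_path, separable):
        import json

        X, y = separable
        bundle = train(X.to_numpy(), y, GTBMParams(), _norm_for(X), seed=0)
        save_bundle(tmp_path / "b", bundle)
        schema = json.loads((tmp_path / "b" / "schema.json").read_text())
        schema["schema_version"] = 99
        (tmp_path / "b" / "schema.json").write_text(json.dumps(schema))
        with pytest.raises(ValueError):
            load_bundle(tmp_path / "b")
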