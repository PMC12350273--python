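"""Random forest and penalized MaxEnt suitability models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from timberzone.evaluation import auc
from timberzone.sdm import (
    FeatureExpansion,
    MaxEntSDM,
    MissingVariableError,
    RandomForestSDM,
    oob_accuracy_pct,
    penalized_nll,
    permutation_importance,
)


def separable_dataset(n=300, seed=0, noise_cols=2):
    """Presence exactly where MAP > 1200 mm; other columns uninformative."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "MAP": rng.uniform(600, 1800, n),
        "TD": rng.uniform(15, 30, n),
    })
    for k in range(noise_cols):
        table[f"noise{k}"] = rng.normal(size=n)
    labels = (table["MAP"] > 1200).astype(int).to_numpy()
    return table, labels


class TestRandomForest:
    def test_separable_truth_recovered(self):
        table, labels = separable_dataset(seed=1)
        res = RandomForestSDM(table, labels, n_trees=200, seed=0).fit()
        assert res.holdout.auc >= 0.99
        assert res.importance["importance"].idxmax() == "MAP"

    def test_shuffled_labels_auc_near_half(self):
        """Permutation null: mean holdout AUC over 20 shuffles in 0.5 +/- 0.1."""
        table, labels = separable_dataset(n=200, seed=2)
        rng = np.random.default_rng(7)
        aucs = []
        for rep in range(20):
            res = RandomForestSDM(table, rng.permutation(labels),
                                  n_trees=60, seed=rep).fit()
            aucs.append(res.holdout.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_noise_feature_never_outranks_signal(self):
        table, labels = separable_dataset(seed=3)
        res = RandomForestSDM(table, labels, n_trees=200, seed=1).fit()
        imp = res.importance["importance"]
        assert imp["MAP"] >= imp["noise0"]
        assert imp["MAP"] >= imp["noise1"]

    def test_same_seed_identical_model(self):
        table, labels = separable_dataset(n=150, seed=4)
        a = RandomForestSDM(table, labels, n_trees=50, seed=5).fit()
        b = RandomForestSDM(table, labels, n_trees=50, seed=5).fit()
        assert a.oob_error == b.oob_error
        np.testing.assert_array_equal(a.predict(table), b.predict(table))

    def test_single_class_training_rejected(self):
        table, _ = separable_dataset(n=60, seed=5)
        with pytest.raises(ValueError, match="class"):
            RandomForestSDM(table, np.ones(60, int), n_trees=20).fit()

    def test_oob_and_holdout_error_agree_on_large_sample(self):
        table, labels = separable_dataset(n=600, seed=6)
        res = RandomForestSDM(table, labels, n_trees=300, seed=0).fit()
        holdout_err = 1.0 - res.holdout.accuracy
        assert abs(res.oob_error - holdout_err) <= 0.1

    def test_accuracy_is_oob_complement(self):
        assert oob_accuracy_pct(10.03) == pytest.approx(89.97)

    def test_summary_renders(self):
        table, labels = separable_dataset(n=120, seed=7)
        res = RandomForestSDM(table, labels, n_trees=30, seed=0).fit()
        text = res.summary()
        assert "OOB" in text and "MAP" in text


class TestRandomForestSurface(object):
    def test_prediction_on_grid(self, small_grid, truth_surface):
        rng = np.random.default_rng(0)
        rows, cols = np.nonzero(small_grid.valid)
        take = rng.choice(rows.size, 250, replace=False)
        table = small_grid.table(rows[take], cols[take])
        labels = (truth_surface.values[rows[take], cols[take]]
                  > 0.5).astype(int)
        res = RandomForestSDM(table, labels, n_trees=100, seed=0).fit()
        surf = res.predict_surface(small_grid)
        assert surf.values.min() >= 0.0 and surf.values.max() <= 1.0
        assert surf.model_tag == "RF"
        # row-extraction oracle on three cells
        for r, c in [(0, 0), (3, 5), (10, 20)]:
            row = small_grid.table(np.array([r]), np.array([c]))
            assert surf.values[r, c] == pytest.approx(res.predict(row)[0])

    def test_missing_variable_schema_error(self, small_grid):
        table, labels = separable_dataset(n=100, seed=1)
        res = RandomForestSDM(table, labels, n_trees=20, seed=0).fit()
        bad = small_grid.copy()
        del bad.variables["MAP"]
        with pytest.raises(MissingVariableError, match="MAP"):
            res.predict_surface(bad)


class TestMaxEnt:
    def test_separating_binary_feature_direction(self):
        rng = np.random.default_rng(0)
        background = pd.DataFrame({"ind": (rng.uniform(size=400) < 0.05)
                                   .astype(float)})
        presence = pd.DataFrame({"ind": np.ones(40)})
        res = MaxEntSDM(presence, background,
                        feature_classes=("linear",), cv_folds=2,
                        seed=0).fit(run_cv=False)
        s1 = res.predict(pd.DataFrame({"ind": [1.0]}))[0]
        s0 = res.predict(pd.DataFrame({"ind": [0.0]}))[0]
        assert s1 > s0

    def test_no_signal_shrinks_flat(self):
        rng = np.random.default_rng(5)
        background = pd.DataFrame(rng.normal(size=(400, 4)),
                                  columns=list("ABCD"))
        presence = background.iloc[rng.choice(400, 60, replace=False)]
        res = MaxEntSDM(presence, background, cv_folds=2,
                        seed=0).fit(run_cv=False)
        p = res.predict(background)
        assert p.max() - p.min() <= 0.1

    def test_one_dim_coefficient_matches_brute_force_scan(self):
        """The fitted linear coefficient agrees with an independent
        grid-search maximizer of the penalized presence-background
        likelihood on a 20-cell toy landscape."""
        rng = np.random.default_rng(1)
        background = pd.DataFrame({"x": np.linspace(0, 10, 20)})
        presence = pd.DataFrame({"x": rng.uniform(6, 10, 15)})
        model = MaxEntSDM(presence, background, feature_classes=("linear",),
                          cv_folds=2, seed=0)
        res = model.fit(run_cv=False)
        X = res.expansion.transform(
            pd.concat([presence, background], ignore_index=True))
        y = np.r_[np.ones(len(presence)), np.zeros(len(background))]

        def profiled(w):
            b = minimize_scalar(
                lambda b: penalized_nll(np.array([w]), b, X, y, model.alpha),
                bounds=(-20, 20), method="bounded",
                options={"xatol": 1e-10}).x
            return penalized_nll(np.array([w]), b, X, y, model.alpha)

        grid = np.linspace(-2, 15, 3401)  # step 0.005
        w_star = grid[np.argmin([profiled(w) for w in grid])]
        # refine around the coarse optimum
        fine = np.linspace(w_star - 0.01, w_star + 0.01, 2001)
        w_star = fine[np.argmin([profiled(w) for w in fine])]
        assert res.coefs.iloc[0] == pytest.approx(w_star, abs=1e-3)

    def test_contributions_sum_to_hundred(self):
        table, labels = separable_dataset(n=250, seed=2)
        res = MaxEntSDM(table[labels == 1], table[labels == 0],
                        cv_folds=2, seed=0).fit(run_cv=False)
        assert res.contribution.sum() == pytest.approx(100.0, abs=0.1)
        assert (res.contribution >= 0).all()

    def test_cv_metrics_reported(self):
        table, labels = separable_dataset(n=200, seed=3)
        res = MaxEntSDM(table[labels == 1], table[labels == 0],
                        cv_folds=5, seed=0).fit()
        assert 0.9 <= res.cv_summary["auc"][0] <= 1.0
        assert len(res.cv_metrics) == 5

    def test_too_few_presences_rejected(self):
        bg = pd.DataFrame({"x": np.arange(30.0)})
        with pytest.raises(ValueError, match="presence"):
            MaxEntSDM(bg.head(5), bg)

    def test_surface_in_unit_interval_and_order_invariant(self, small_grid,
                                                          truth_surface):
        rng = np.random.default_rng(2)
        rows, cols = np.nonzero(small_grid.valid)
        pres_idx = rng.choice(rows.size, 60, replace=False,
                              p=(truth_surface.values[rows, cols]
                                 / truth_surface.values[rows, cols].sum()))
        bg_idx = rng.choice(rows.size, 200, replace=False)
        pres = small_grid.table(rows[pres_idx], cols[pres_idx])
        bg = small_grid.table(rows[bg_idx], cols[bg_idx])
        res = MaxEntSDM(pres, bg, cv_folds=2, seed=0).fit(run_cv=False)
        surf = res.predict_surface(small_grid)
        assert surf.values.min() >= 0.0 and surf.values.max() <= 1.0
        shuffled = small_grid.copy()
        shuffled.variables = dict(reversed(list(shuffled.variables.items())))
        surf2 = res.predict_surface(shuffled)
        np.testing.assert_array_equal(surf.values, surf2.values)


class TestFeatureExpansion:
    def test_hinge_and_product_feature_counts(self):
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.uniform(size=(50, 3)), columns=list("abc"))
        exp = FeatureExpansion.build(bg, bg, n_hinge_knots=5)
        # 3 linear + 3 quadratic + 3 products + <=15 hinges
        n_hinges = sum(len(v) for v in exp.knots.values())
        assert len(exp.feature_names) == 3 + 3 + 3 + n_hinges
        assert exp.transform(bg).shape == (50, len(exp.feature_names))

    def test_linear_features_scaled_to_unit_range(self):
        bg = pd.DataFrame({"x": [0.0, 5.0, 10.0]})
        exp = FeatureExpansion.build(bg, bg, classes=("linear",))
        out = exp.transform(bg)
        np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])


class TestPermutationImportance:
    def test_constant_column_scores_zero(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.normal(size=100),
                              "const": np.ones(100)})
        labels = (table["x"] > 0).astype(int).to_numpy()

        def predict(frame):
            return expit(frame["x"].to_numpy())

        imp = permutation_importance(predict, table, labels,
                                     lambda s, l: auc(s, l), repeats=3)
        assert imp.loc["const", "importance"] == 0.0
        assert imp.loc["x", "importance"] > 0.2

    def test_two_seeds_agree_within_pooled_error(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": rng.normal(size=150),
                              "z": rng.normal(size=150)})
        labels = ((table["x"] + 0.5 * rng.normal(size=150)) > 0
                  ).astype(int).to_numpy()

        def predict(frame):
            return expit(frame["x"].to_numpy())

        a = permutation_importance(predict, table, labels,
                                   lambda s, l: auc(s, l), seed=1, repeats=50)
        b = permutation_importance(predict, table, labels,
                                   lambda s, l: auc(s, l), seed=2, repeats=50)
        for var in table.columns:
            pooled = np.hypot(a.loc[var, "sd"], b.loc[var, "sd"]) / np.sqrt(50)
            diff = abs(a.loc[var, "importance"] - b.loc[var, "importance"])
            assert diff <= max(2 * pooled, 1e-12)

    def test_repeats_must_be_positive(self):
        with pytest.raises(ValueError, match="repeats"):
            permutation_importance(lambda f: None, pd.DataFrame({"x": [1.0]}),
                                   [1], lambda s, l: 0.0, repeats=0)
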