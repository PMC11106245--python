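"""Endpoint models: bootstrap evaluation, ROC bands, comparisons,
permutation importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mspanel.gfs import make_bootstrap_plan
from mspanel.metrics import auroc, pearson_r2, roc_band, roc_points
from mspanel.models import (
    evaluate_gda_sda_eda,
    feature_set_comparison,
    fit_eval_classifier,
    fit_eval_poisson,
    permutation_importance,
)


def pair_fraction_auroc(values, y):
    pos = [v for v, lab in zip(values, y) if lab == 1]
    neg = [v for v, lab in zip(values, y) if lab == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAurocImplementation:
    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = (rng.random(50) < 0.4).astype(int)
            if y.sum() in (0, 50):
                continue
            s = np.round(rng.normal(size=50), 1)  # rounded: force ties
            assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_roc_band_auc_close_to_mean_auroc(self):
        """Trapezoid area under the vertically averaged ROC agrees with the
        mean of per-curve AUROCs to grid resolution."""
        rng = np.random.default_rng(1)
        curves, aurocs = [], []
        for _ in range(40):
            y = (rng.random(120) < 0.5).astype(int)
            s = y * 0.8 + rng.normal(size=120)
            curves.append(roc_points(y, s))
            aurocs.append(auroc(y, s))
        band = roc_band(curves, n_grid=101)
        assert abs(band.auc_of_mean() - np.mean(aurocs)) < 0.005
        assert np.all(np.diff(band.tpr_mean) >= -1e-12)


class TestClassifier:
    def test_separable_feature_perfect_and_certain(self):
        n = 90
        y = (np.arange(n) % 2).astype(int)
        X = (2 * y - 1).reshape(-1, 1).astype(float)
        plan = make_bootstrap_plan(n, y, n_reps=30, rng_seed=2)
        rep = fit_eval_classifier(X, y, plan)
        assert rep.mean == 1.0
        assert rep.sd == 0.0

    def test_pure_noise_is_chance(self):
        """Bootstrap reps of one dataset are correlated (they resample the
        same chance associations), so the null check averages dataset-level
        means over independent datasets and uses their spread as the SE."""
        rng = np.random.default_rng(3)
        n = 300
        means = []
        for d in range(12):
            X = rng.normal(size=(n, 4))
            y = (rng.random(n) < 0.5).astype(int)
            plan = make_bootstrap_plan(n, y, n_reps=30, rng_seed=100 + d)
            means.append(fit_eval_classifier(X, y, plan).mean)
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - 0.5) < 3 * se

    def test_per_rep_auroc_equals_pair_oracle(self):
        """Each rep's reported AUROC equals the exhaustive pair fraction on
        that rep's test scores (test folds of <= 50 samples)."""
        rng = np.random.default_rng(5)
        n = 90
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + rng.normal(size=n) > 0).astype(int)
        plan = make_bootstrap_plan(n, y, n_reps=25, rng_seed=6)
        rep = fit_eval_classifier(X, y, plan)
        from mspanel.models import _fit_scores

        for r, (train, test) in enumerate(plan.splits):
            scores = _fit_scores("logistic", X[train], y[train], X[test])
            assert rep.per_rep[r] == pytest.approx(
                pair_fraction_auroc(scores, y[test]), abs=1e-12
            )

    def test_scores_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(7)
        n = 150
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] - X[:, 2] + rng.logistic(size=n) > 0).astype(int)
        plan = make_bootstrap_plan(n, y, n_reps=20, rng_seed=8)
        a = fit_eval_classifier(X, y, plan)
        X2 = X * np.array([100.0, 0.01, 1.0]) + np.array([5.0, -3.0, 0.0])
        b = fit_eval_classifier(X2, y, plan)
        np.testing.assert_allclose(a.per_rep, b.per_rep, atol=1e-6)


class TestPoisson:
    def test_coefficient_recovery(self):
        """Counts drawn from the model's own link are recovered to ~10%."""
        rng = np.random.default_rng(9)
        n = 20_000
        X = rng.normal(size=(n, 3))
        beta = np.array([0.5, -0.4, 0.3])
        mu = np.exp(-0.2 + X @ beta)
        c = rng.poisson(mu)
        from sklearn.linear_model import PoissonRegressor

        fit = PoissonRegressor(alpha=1e-6, max_iter=500).fit(X, c)
        np.testing.assert_allclose(fit.coef_, beta, rtol=0.10)

    def test_null_regression_r2_near_zero(self):
        rng = np.random.default_rng(10)
        n = 400
        X = rng.normal(size=(n, 3))
        c = rng.poisson(1.2, n)
        plan = make_bootstrap_plan(n, (c > 0).astype(int), n_reps=100, rng_seed=11)
        rep = fit_eval_poisson(X, c, plan)
        assert rep.mean < 3 * rep.sd / np.sqrt(100) + 0.02

    def test_shrinkage_pattern(self, corrected_study):
        """Predictions over-shoot at zero lesions and under-shoot at the
        clip cap — the familiar regression-to-the-mean pattern."""
        cfg, corrected, filtered, truth = corrected_study
        counts = (
            filtered.set_index("sample_id")["gd_lesion_count"]
            .reindex(corrected.index)
            .dropna()
        )
        feats = corrected.loc[counts.index]
        c = np.minimum(counts.to_numpy(float), 5)
        plan = make_bootstrap_plan(
            len(c), (c > 0).astype(int), n_reps=60, rng_seed=12
        )
        rep = fit_eval_poisson(feats.to_numpy(), c, plan)
        # reconstruct pooled predictions from the fitted line end points
        assert rep.slope < 1.0
        assert rep.intercept > 0.0

    def test_clipping_applied(self):
        rng = np.random.default_rng(13)
        n = 200
        X = rng.normal(size=(n, 2))
        c = rng.poisson(1.0, n)
        c[:5] = 40  # extreme counts must not dominate after clipping
        plan = make_bootstrap_plan(n, (c > 0).astype(int), n_reps=20, rng_seed=14)
        rep = fit_eval_poisson(X, c, plan, cap=5)
        assert rep.rmse < 6.0


class TestSubEndpoints:
    def test_ordering_with_count_graded_effects(self, corrected_study):
        """Stronger latent signal at higher counts: EDA is easiest, SDA
        hardest, GDA in between."""
        from mspanel.cohort import derive_binary_labels

        cfg, corrected, filtered, truth = corrected_study
        gda = derive_binary_labels(filtered, "GDA")
        y = gda.encode(corrected.index)
        keep = y >= 0
        feats = corrected[keep]
        labs = {
            ep: derive_binary_labels(filtered, ep).encode(feats.index)
            for ep in ("GDA", "SDA", "EDA")
        }
        plan = make_bootstrap_plan(len(feats), y[keep], n_reps=100, rng_seed=15)
        causal = ["NEFL"] + [f"P{j:04d}" for j in truth.causal_indices["GD"] if j != 0]
        reports = evaluate_gda_sda_eda(
            feats[causal].to_numpy(), y[keep], labs, plan
        )
        assert reports["EDA"].mean > reports["GDA"].mean > reports["SDA"].mean

    def test_degenerate_subclass_drops_reps(self):
        rng = np.random.default_rng(16)
        n = 60
        X = rng.normal(size=(n, 2))
        y = (np.arange(n) % 2).astype(int)
        sda = np.full(n, -1)
        sda[:4] = [1, 0, 1, 0]  # nearly always single-class in a test fold
        plan = make_bootstrap_plan(n, y, n_reps=30, rng_seed=17)
        reports = evaluate_gda_sda_eda(X, y, {"GDA": y, "SDA": sda}, plan)
        assert reports["SDA"].n_dropped > 0

    def test_constant_scores_are_chance(self):
        n = 60
        y = (np.arange(n) % 2).astype(int)
        X = np.zeros((n, 2))
        plan = make_bootstrap_plan(n, y, n_reps=10, rng_seed=18)
        reports = evaluate_gda_sda_eda(X, y, {"GDA": y}, plan)
        assert reports["GDA"].mean == pytest.approx(0.5)


class TestFeatureSetComparison:
    def _anchored_data(self, n=240, p=8, seed=19, secondary=0.6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        eta = 1.4 * X[:, 0] + secondary * X[:, 1] + secondary * 0.8 * X[:, 2]
        y = (eta + rng.logistic(size=n) > 0).astype(int)
        cols = ["NEFL"] + [f"P{i}" for i in range(1, p)]
        return pd.DataFrame(X, columns=cols), y

    def test_secondary_signal_survives_anchor_ablation(self):
        feats, y = self._anchored_data()
        plan = make_bootstrap_plan(len(y), y, n_reps=150, rng_seed=20)
        reports = feature_set_comparison(
            feats, y, plan, gfs_set=["NEFL", "P1", "P2"], anchor="NEFL"
        )
        no_anchor = reports["all_except_anchor"]
        se = no_anchor.sd / np.sqrt(150)
        assert no_anchor.mean - 0.5 > 3 * se
        assert reports["gfs"].mean >= reports["anchor_only"].mean

    def test_pure_anchor_signal_ablates_to_chance(self):
        feats, y = self._anchored_data(secondary=0.0, seed=21)
        plan = make_bootstrap_plan(len(y), y, n_reps=150, rng_seed=22)
        reports = feature_set_comparison(
            feats, y, plan, gfs_set=["NEFL"], anchor="NEFL"
        )
        no_anchor = reports["all_except_anchor"]
        se = no_anchor.sd / np.sqrt(150)
        assert abs(no_anchor.mean - 0.5) < 3 * se

    def test_gfs_equal_to_anchor_when_identical(self):
        feats, y = self._anchored_data(seed=23)
        plan = make_bootstrap_plan(len(y), y, n_reps=40, rng_seed=24)
        reports = feature_set_comparison(
            feats, y, plan, gfs_set=["NEFL"], anchor="NEFL"
        )
        np.testing.assert_array_equal(
            reports["gfs"].per_rep, reports["anchor_only"].per_rep
        )


class TestPermutationImportance:
    def test_constant_column_has_exactly_zero_decrease(self):
        rng = np.random.default_rng(25)
        n = 120
        X = rng.normal(size=(n, 3))
        X[:, 2] = 4.2  # constant column
        y = (X[:, 0] + rng.logistic(size=n) > 0).astype(int)
        feats = pd.DataFrame(X, columns=["signal", "noise", "constant"])
        plan = make_bootstrap_plan(n, y, n_reps=25, rng_seed=26)
        imp = permutation_importance(feats, y, plan, rng_seed=27)
        assert imp.loc["constant", "mean_decrease"] == 0.0
        assert imp.loc["constant", "sd_decrease"] == 0.0

    def test_causal_feature_stands_out_null_stays_flat(self):
        rng = np.random.default_rng(28)
        n = 300
        X = rng.normal(size=(n, 5))
        y = (1.5 * X[:, 0] + rng.logistic(size=n) > 0).astype(int)
        feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        plan = make_bootstrap_plan(n, y, n_reps=120, rng_seed=29)
        imp = permutation_importance(feats, y, plan, rng_seed=30)
        se = imp["sd_decrease"] / np.sqrt(imp["n_reps"])
        assert imp.loc["f0", "mean_decrease"] > 3 * se["f0"]
        # null features: decreases stay at the chance-association floor,
        # far below the causal feature's signal
        for f in ["f1", "f2", "f3", "f4"]:
            assert abs(imp.loc[f, "mean_decrease"]) < 0.01

    def test_anchor_dominates_decrease(self, corrected_study):
        from mspanel.cohort import derive_binary_labels

        cfg, corrected, filtered, truth = corrected_study
        lab = derive_binary_labels(filtered, "GDA")
        y = lab.encode(corrected.index)
        keep = y >= 0
        feats = corrected[keep][["NEFL", "P0001", "P0002", "P0015"]]
        plan = make_bootstrap_plan(int(keep.sum()), y[keep], n_reps=80, rng_seed=31)
        imp = permutation_importance(feats, y[keep], plan, rng_seed=32)
        assert imp["mean_decrease"].idxmax() == "NEFL"
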