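"""Randomized-subset importance ensemble: draws, rules, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from mspanel.cohort import BinaryLabeling, derive_binary_labels
from mspanel.exceptions import DegenerateImportanceError, ParameterError
from mspanel.screen import (
    ScreenConfig,
    aggregate_importance,
    draw_subset,
    model_importance,
    normalize_importance,
    run_screen,
    select_panel,
    train_eval_screen_model,
)


class TestDrawSubset:
    def test_full_pool_and_anchor_only(self):
        ids = [f"p{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        assert sorted(draw_subset(ids, 6, "p2", rng)) == sorted(ids)
        assert draw_subset(ids, 1, "p2", rng) == ["p2"]

    def test_oversized_subset_rejected(self):
        with pytest.raises(ParameterError):
            draw_subset(["a", "b"], 3, "a", np.random.default_rng(0))

    def test_uniformity_chi_square(self):
        """10^5 size-3 draws from 20 proteins: every non-anchor appears
        with frequency 2/19 within 3 binomial SE, and the chi-square
        goodness-of-fit does not reject uniformity."""
        ids = [f"p{i}" for i in range(20)]
        rng = np.random.default_rng(5)
        n_draws = 100_000
        counts = {p: 0 for p in ids if p != "p0"}
        for _ in range(n_draws):
            for p in draw_subset(ids, 3, "p0", rng)[1:]:
                counts[p] += 1
        freq = np.array(list(counts.values())) / n_draws
        expect = 2 / 19
        se = np.sqrt(expect * (1 - expect) / n_draws)
        assert np.all(np.abs(freq - expect) < 3 * se)
        chi2 = ((np.array(list(counts.values())) - n_draws * expect) ** 2 / (n_draws * expect)).sum()
        assert stats.chi2(df=18).sf(chi2) > 0.001


class TestImportanceRules:
    def test_logistic_zero_coef_and_sd_weighting(self):
        class Fake:
            coef_ = np.array([[0.0, 4.0]])

        np.testing.assert_allclose(
            model_importance("logistic", Fake(), np.array([1.0, 1.0])), [0.0, 4.0]
        )

        class Fake2:
            coef_ = np.array([[2.0, 2.0]])

        np.testing.assert_allclose(
            model_importance("logistic", Fake2(), np.array([1.0, 3.0])), [2.0, 6.0]
        )

    def test_svc_requires_linear_kernel(self):
        class FakeSVC:
            coef_ = np.array([[1.0, -2.0]])
            kernel = "rbf"

        with pytest.raises(ParameterError):
            model_importance("linear_svc", FakeSVC(), np.array([1.0, 1.0]))

    def test_forest_concentrates_on_informative_feature(self):
        rng = np.random.default_rng(2)
        n = 500
        signal = rng.normal(size=n)
        y = (signal > 0).astype(int)
        X = np.column_stack([signal, rng.normal(size=n)])
        rf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        imp = model_importance("random_forest", rf, np.ones(2))
        assert normalize_importance(imp)[0] > 0.9

    def test_normalize(self):
        np.testing.assert_allclose(normalize_importance([2.0, 2.0]), [0.5, 0.5])
        np.testing.assert_allclose(normalize_importance([1.0, 3.0]), [0.25, 0.75])
        with pytest.raises(DegenerateImportanceError):
            normalize_importance([0.0, 0.0])


class TestTrainEval:
    def test_separable_feature_gives_unit_training_auroc(self):
        n = 60
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        feats = pd.DataFrame(
            {"sep": np.r_[np.ones(30), -np.ones(30)], "noise": np.zeros(n)},
            index=[f"s{i}" for i in range(n)],
        )
        _, auroc = train_eval_screen_model(["sep"], feats, y, "logistic")
        assert auroc == 1.0

    def test_training_auroc_overfit_bias_on_pure_noise(self):
        """Training AUROC of small logistic models on pure noise exceeds
        0.5 systematically — the optimism the full-data protocol accepts."""
        rng = np.random.default_rng(11)
        n, reps = 400, 200
        aurocs = []
        for _ in range(reps):
            X = rng.normal(size=(n, 3))
            y = (rng.random(n) < 0.5).astype(int)
            feats = pd.DataFrame(X, columns=list("abc"))
            _, a = train_eval_screen_model(list("abc"), feats, y, "logistic")
            aurocs.append(a)
        mean = np.mean(aurocs)
        se = np.std(aurocs, ddof=1) / np.sqrt(reps)
        assert mean - 0.5 > 3 * se

    def test_held_out_variant_removes_most_bias(self):
        rng = np.random.default_rng(13)
        aurocs = []
        for i in range(100):
            X = rng.normal(size=(200, 3))
            y = (rng.random(200) < 0.5).astype(int)
            feats = pd.DataFrame(X, columns=list("abc"))
            _, a = train_eval_screen_model(
                list("abc"), feats, y, "logistic", held_out_fraction=0.33, seed=i
            )
            aurocs.append(a)
        assert abs(np.mean(aurocs) - 0.5) < 3 * np.std(aurocs, ddof=1) / 10


class TestAggregation:
    def test_single_model_arithmetic(self):
        table = aggregate_importance(
            [((0, 1), 0.8, np.array([0.25, 0.75]))], ["a", "b"]
        )
        assert table.loc["a", "importance"] == pytest.approx(0.2)
        assert table.loc["b", "importance"] == pytest.approx(0.6)

    def test_mean_over_containing_models(self):
        records = [
            ((0,), 0.6, np.array([0.5])),
            ((0,), 1.0, np.array([0.1])),
            ((1,), 0.9, np.array([1.0])),
        ]
        table = aggregate_importance(records, ["P", "Q"])
        assert table.loc["P", "importance"] == pytest.approx(0.2)
        assert table.loc["P", "n_models"] == 2

    def test_never_sampled_protein_has_missing_rank(self):
        table = aggregate_importance(
            [((0,), 0.7, np.array([1.0]))], ["a", "ghost"]
        )
        assert np.isnan(table.loc["ghost", "importance"])
        assert np.isnan(table.loc["ghost", "rank"])

    def test_auroc_scaling_linearity(self):
        rng = np.random.default_rng(3)
        records = [
            (rng.choice(6, 3, replace=False), rng.uniform(0.5, 1.0), normalize_importance(rng.random(3)))
            for _ in range(40)
        ]
        ids = list("abcdef")
        base = aggregate_importance(records, ids)["importance"]
        scaled = aggregate_importance(
            [(idx, 0.5 * a, imp) for idx, a, imp in records], ids
        )["importance"]
        pd.testing.assert_series_equal(scaled, 0.5 * base, check_names=False)


@pytest.fixture(scope="module")
def screen_result(corrected_study):
    cfg, corrected, filtered, truth = corrected_study
    labeling = derive_binary_labels(filtered, "GDA")
    config = ScreenConfig(sizes=(3, 6), repeats=60, rng_seed=7)
    table, manifest = run_screen(corrected, labeling, config)
    return table, manifest, truth


class TestRunScreen:
    def test_anchor_in_every_model(self, screen_result):
        table, manifest, _ = screen_result
        assert table.loc["NEFL", "appearances"] == manifest["n_models_sampled"]

    def test_causal_enrichment_in_top_ranks(self, screen_result):
        table, _, truth = screen_result
        causal = {f"P{j:04d}" for j in truth.causal_indices["GD"] if j != 0} | {"NEFL"}
        top5 = set(table.index[:5])
        assert len(top5 & causal) >= 3

    def test_null_data_importances_indistinguishable(self, small_study):
        """With labels shuffled there is no causal structure: 'causal' and
        'non-causal' proteins have statistically equal importances."""
        cfg, expr, table, truth = small_study
        rng = np.random.default_rng(23)
        labeling = derive_binary_labels(table, "CRS")
        shuffled = pd.Series(
            rng.permutation(labeling.labels.to_numpy()), index=labeling.labels.index
        )
        null_lab = BinaryLabeling("CRS", shuffled)
        imp, _ = run_screen(
            expr, null_lab, ScreenConfig(sizes=(3, 6), repeats=80, rng_seed=29)
        )
        causal = [f"P{j:04d}" for j in truth.causal_indices["CRS"] if j != 0]
        noncausal = [
            p for p in imp.index if p not in causal and p != "NEFL"
        ]
        _, p = stats.ttest_ind(
            imp.loc[causal, "importance"], imp.loc[noncausal, "importance"]
        )
        assert p > 0.01


class TestSelectPanel:
    def test_budget_equals_pool(self):
        ranks = {"u": pd.Series([1, 2, 3], index=["a", "b", "c"])}
        assert sorted(select_panel(ranks, budget=3)) == ["a", "b", "c"]

    def test_dominant_protein_selected_first(self):
        ranks = {
            "u1": pd.Series([1, 3, 2], index=["win", "x", "y"]),
            "u2": pd.Series([1, 2, 3], index=["win", "y", "x"]),
        }
        assert select_panel(ranks, budget=1) == ["win"]

    def test_reserved_analyte_appended(self):
        ranks = {"u": pd.Series([1, 2, 3], index=["a", "b", "c"])}
        assert select_panel(ranks, budget=2, reserved=["GFAP"]) == ["a", "b", "GFAP"]

    def test_overlarge_budget_rejected(self):
        ranks = {"u": pd.Series([1], index=["a"])}
        with pytest.raises(ParameterError):
            select_panel(ranks, budget=2)
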