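"""Selection cascade, pipeline grid, grouped CV, and method comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from habitatrad import selection_modeling as sm
from habitatrad import synthetic as syn

warnings.filterwarnings("ignore", category=FutureWarning)


class TestRedundancyFilter:
    def test_exact_duplicate_dropped(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        reduced, report = sm.redundancy_filter(table)
        assert list(reduced.columns) == ["a", "c"]
        dropped = {d["feature"]: d for d in report.dropped_by_redundancy}
        assert dropped["b"]["partner"] == "a"
        assert dropped["b"]["rho"] == pytest.approx(1.0)

    def test_monotone_transform_dropped(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "cube": x**3})
        reduced, _ = sm.redundancy_filter(table)
        assert list(reduced.columns) == ["a"]

    def test_constant_feature_dropped_with_reason(self, rng):
        table = pd.DataFrame({"k": np.full(20, 3.0), "a": rng.normal(size=20)})
        reduced, report = sm.redundancy_filter(table)
        assert list(reduced.columns) == ["a"]
        assert report.dropped_by_redundancy[0]["reason"] == "constant"

    def test_independent_features_survive(self, rng):
        table = pd.DataFrame(rng.normal(size=(200, 20)))
        table.columns = [f"f{i}" for i in range(20)]
        reduced, _ = sm.redundancy_filter(table)
        assert reduced.shape[1] == 20


class TestUnivariateFilter:
    def test_complete_separation_kept(self, rng):
        labels = pd.Series(["NSCLC"] * 20 + ["BID"] * 20)
        table = pd.DataFrame(
            {"sep": np.r_[np.ones(20), np.zeros(20)] + rng.normal(0, 0.01, 40),
             "noise": rng.normal(size=40)}
        )
        report = sm.SelectionReport()
        kept = sm.univariate_filter(table, labels, report=report)
        assert "sep" in kept.columns

    def test_routing_recorded(self, rng):
        labels = pd.Series(["NSCLC"] * 50 + ["BID"] * 50)
        normal = rng.normal(size=100)
        heavy = rng.standard_cauchy(size=100)
        table = pd.DataFrame({"normal": normal, "heavy": heavy})
        report = sm.SelectionReport()
        sm.univariate_filter(table, labels, report=report)
        tests = {r["feature"]: r["test"] for r in report.univariate}
        assert tests["normal"] == "ttest"
        assert tests["heavy"] == "mannwhitney"

    def test_tiny_class_skips_gate(self, rng):
        labels = pd.Series(["NSCLC"] * 2 + ["BID"] * 30)
        table = pd.DataFrame({"a": rng.normal(size=32)})
        report = sm.SelectionReport()
        sm.univariate_filter(table, labels, report=report)
        assert report.univariate[0]["test"] == "mannwhitney"

    def test_literal_gate_inverts_routing(self, rng):
        labels = pd.Series(["NSCLC"] * 50 + ["BID"] * 50)
        table = pd.DataFrame({"normal": rng.normal(size=100)})
        report = sm.SelectionReport()
        sm.univariate_filter(table, labels, gate="literal", report=report)
        assert report.univariate[0]["test"] == "mannwhitney"

    def test_null_keep_rate_near_alpha(self, rng):
        # ~5% of pure-noise features pass at alpha = .05
        labels = pd.Series(["NSCLC"] * 100 + ["BID"] * 100)
        table = pd.DataFrame(
            rng.normal(size=(200, 400)), columns=[f"f{i}" for i in range(400)]
        )
        kept = sm.univariate_filter(table, labels)
        assert 0.02 <= kept.shape[1] / 400 <= 0.09


class TestModelBasedSelection:
    @pytest.mark.parametrize("selector", sm.SELECTORS)
    def test_informative_feature_recovered(self, selector, rng):
        labels = pd.Series(["NSCLC"] * 30 + ["BID"] * 30)
        table = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"f{i}" for i in range(10)])
        table["info"] = np.r_[np.ones(30), np.zeros(30)] * 4 + rng.normal(0, 0.5, 60)
        kept = sm.model_based_select(table, labels, selector, seed=0)
        assert "info" in kept
        assert set(kept) <= set(table.columns)

    def test_lasso_empty_set_falls_back_to_top1(self, rng):
        # pure-noise labels push the CV-chosen penalty to drop everything
        labels = pd.Series(np.where(rng.random(40) < 0.5, "NSCLC", "BID"))
        table = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        kept = sm.model_based_select(table, labels, "lasso", seed=0)
        assert len(kept) >= 1


class TestGridAndCv:
    def test_grid_enumerates_18_unique_pipelines(self):
        grid = sm.pipeline_grid()
        assert len(grid) == 18
        assert len({(p.selector, p.classifier) for p in grid}) == 18

    def test_aggregation_examples(self):
        assert sm.aggregate_lesion_prediction([0.2, 0.8]) == pytest.approx(0.5)
        assert sm.aggregate_lesion_prediction([0.7]) == pytest.approx(0.7)
        assert sm.aggregate_lesion_prediction([0.1, 0.5, 0.9]) == pytest.approx(
            sm.aggregate_lesion_prediction([0.9, 0.1, 0.5])
        )

    def test_f1_threshold_tie_breaks_toward_half(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.2, 0.1])
        assert sm.f1_optimal_threshold(y, s) == pytest.approx(0.5)

    def test_folds_group_lesions_and_stratify(self):
        X, y, lesions = syn.make_feature_cohort(n_per_class=10, seed=1)
        folds = sm.make_lesion_folds(lesions, y, n_folds=5, seed=0)
        for train, test in folds:
            assert not set(lesions[train]) & set(lesions[test])
            assert set(y[test].unique()) == {"NSCLC", "BID"}

    def test_too_few_lesions_rejected(self):
        X, y, lesions = syn.make_feature_cohort(n_per_class=3, seed=1)
        with pytest.raises(ValueError):
            sm.make_lesion_folds(lesions, y, n_folds=5)

    def test_selection_blind_to_test_fold_labels(self):
        # no-leakage: permuting labels of the held-out lesions cannot change
        # what the training fold selects
        X, y, lesions = syn.make_feature_cohort(n_per_class=8, n_features=12, seed=2)
        folds = sm.make_lesion_folds(lesions, y, n_folds=4, seed=0)
        train, test = folds[0]
        y_perm = y.copy()
        y_perm.iloc[test] = np.random.default_rng(0).permutation(y.iloc[test].values)
        kept1, _ = sm._fit_cascade(
            X.iloc[train].reset_index(drop=True), y.iloc[train].reset_index(drop=True),
            "lasso", 0, "conventional",
        )
        kept2, _ = sm._fit_cascade(
            X.iloc[train].reset_index(drop=True), y_perm.iloc[train].reset_index(drop=True),
            "lasso", 0, "conventional",
        )
        assert kept1 == kept2

    def test_separable_cohort_reaches_high_auc(self):
        X, y, lesions = syn.make_feature_cohort(n_per_class=12, effect_size=4.0, seed=3)
        folds = sm.make_lesion_folds(lesions, y, n_folds=3, seed=0)
        rep = sm.evaluate_pipeline(X, y, lesions, sm.PipelineSpec("lasso", "logistic_regression"), folds)
        assert rep.mean["auc"] >= 0.99
        assert set(rep.fold_metrics.columns) >= {"auc", "accuracy", "sensitivity", "specificity"}
        assert ((rep.fold_metrics[["auc", "accuracy"]] >= 0) & (rep.fold_metrics[["auc", "accuracy"]] <= 1)).all().all()

    def test_reproducible_given_seed(self):
        X, y, lesions = syn.make_feature_cohort(n_per_class=8, seed=4)
        folds = sm.make_lesion_folds(lesions, y, n_folds=3, seed=5)
        r1 = sm.evaluate_pipeline(X, y, lesions, sm.PipelineSpec("random_forest", "gbdt", seed=5), folds)
        r2 = sm.evaluate_pipeline(X, y, lesions, sm.PipelineSpec("random_forest", "gbdt", seed=5), folds)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)


class TestComparison:
    def _reports(self, aucs_by_method):
        out = {}
        for method, aucs in aucs_by_method.items():
            reports = {}
            for (spec, auc) in zip(sm.pipeline_grid(), aucs):
                fm = pd.DataFrame(
                    {"auc": [auc], "accuracy": [0.8], "sensitivity": [0.8],
                     "specificity": [0.8], "threshold": [0.5], "n_features": [3]},
                    index=pd.Index([0], name="fold"),
                )
                reports[spec.name] = sm.CvReport(pipeline=spec, fold_metrics=fm)
            out[method] = reports
        return out

    def test_self_comparison_p_is_one(self, rng):
        aucs = rng.uniform(0.6, 0.9, 18)
        reports = self._reports({"a": aucs, "b": aucs.copy()})
        comp = sm.compare_methods(reports)
        assert comp.pairwise_p.loc["a", "b"] == 1.0

    def test_constant_shift_detected(self, rng):
        base = rng.uniform(0.6, 0.8, 18)
        jitter = rng.normal(0, 1e-4, 18)
        reports = self._reports({"a": base, "b": base + 0.05 + jitter})
        comp = sm.compare_methods(reports)
        assert comp.pairwise_p.loc["a", "b"] < 0.001
        assert comp.summary.loc["b", "mean_auc"] > comp.summary.loc["a", "mean_auc"]

    def test_one_row_per_method_with_sd(self, rng):
        reports = self._reports({m: rng.uniform(0.5, 1.0, 18) for m in ("x", "y", "z")})
        comp = sm.compare_methods(reports)
        assert list(comp.summary.index) == ["x", "y", "z"]
        assert {"mean_auc", "sd_auc"} <= set(comp.summary.columns)

    def test_mismatched_grids_rejected(self, rng):
        reports = self._reports({"a": rng.uniform(0.5, 1.0, 18), "b": rng.uniform(0.5, 1.0, 18)})
        del reports["b"]["svm_rfe+svm"]
        with pytest.raises(ValueError):
            sm.compare_methods(reports)
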